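"""Synthetic genomes with planted diverged repeat families, and recovery scoring.

The generator emulates the artificial-sequence experiments used to map the
method's detection limits: random background DNA of a given length into
which N_a copies of a random mother sequence of length L_a are planted.
Each copy carries a fixed number ``round(0.5 * x * L_a)`` of random base
substitutions (at distinct positions, each to a different base), so that the
expected pairwise divergence between two copies is x substitutions per
nucleotide, plus on average one indel (random size 1-5) per 50 bases
(Poisson count, insertion/deletion equally likely).

The two-family design plants two families of internally identical copies
whose mothers are placed at a controlled mutual divergence ``x_between``
(each mother receives ``round(0.5 * x_between * L_a)`` substitutions from a
common ancestor; above the distinct-position capacity the substitutions are
applied sequentially with replacement, so realised divergence saturates the
way repeated random mutation does).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genome import GenomeIndex, from_records, decode

RECORD_NAME = "synthetic"


@dataclass
class PlantedCopy:
    """One planted repeat instance (1-based inclusive coordinates)."""

    start: int
    end: int
    family: int
    strand: str = "+"
    n_subs: int = 0
    n_indels: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PlantedTruth:
    """Ground truth of a planted-repeat genome."""

    mothers: list[str]
    copies: list[PlantedCopy]
    length: int
    L_a: int
    x: float
    seed: int

    def to_json(self, path) -> None:
        payload = {"mothers": self.mothers,
                   "copies": [asdict(c) for c in self.copies],
                   "length": self.length, "L_a": self.L_a, "x": self.x,
                   "seed": self.seed}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(mothers=d["mothers"],
                   copies=[PlantedCopy(**c) for c in d["copies"]],
                   length=d["length"], L_a=d["L_a"], x=d["x"], seed=d["seed"])

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.copies:
                fh.write(f"{RECORD_NAME}\t{c.start - 1}\t{c.end}\t"
                         f"family{c.family}\t0\t{c.strand}\n")


_BASES = np.arange(4, dtype=np.int8)


def _random_seq(rng, n, freq=None) -> np.ndarray:
    p = np.full(4, 0.25) if freq is None else np.asarray(freq, dtype=float)
    return rng.choice(_BASES, size=n, p=p).astype(np.int8)


def mutate_copy(mother: np.ndarray, n_subs: int, n_indels: int,
                rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Substitutions at distinct positions plus indels of size 1-5."""
    seq = mother.copy()
    L = len(seq)
    if n_subs > 0:
        if n_subs <= L:
            pos = rng.choice(L, size=n_subs, replace=False)
        else:
            pos = rng.integers(0, L, size=n_subs)
        for p in pos:
            seq[p] = (seq[p] + 1 + rng.integers(0, 3)) % 4
    out = list(seq)
    applied = 0
    for _ in range(n_indels):
        size = int(rng.integers(1, 6))
        if rng.random() < 0.5 and len(out) > size + 1:  # deletion
            p = int(rng.integers(0, len(out) - size))
            del out[p : p + size]
        else:  # insertion
            p = int(rng.integers(0, len(out) + 1))
            out[p:p] = list(_random_seq(rng, size))
        applied += 1
    return np.asarray(out, dtype=np.int8), applied


def _place_copies(length: int, copies: list[np.ndarray],
                  rng: np.random.Generator, freq=None):
    """Uniform non-overlapping placement via the sorted-gap construction."""
    total = sum(len(c) for c in copies)
    free = length - total
    if free <= 0:
        raise ValueError("planted copies do not fit in the requested length")
    anchors = np.sort(rng.integers(0, free + 1, size=len(copies)))
    genome = _random_seq(rng, length, freq)
    intervals = []
    shift = 0
    for anchor, copy in zip(anchors, copies):
        start = int(anchor) + shift  # 0-based
        genome[start : start + len(copy)] = copy
        intervals.append((start + 1, start + len(copy)))
        shift += len(copy)
    return genome, intervals


def make_planted_genome(length: int = 4_000_000, L_a: int = 600,
                        N_a: int = 500, x: float = 1.0, seed: int = 0,
                        background_freq=None, indel_rate: float = 1 / 50.0,
                        revcomp_fraction: float = 0.0,
                        ) -> tuple[GenomeIndex, PlantedTruth]:
    """Random genome with N_a diverged copies of one mother sequence.

    Each copy carries ``round(0.5 * x * L_a)`` substitutions (pairwise
    divergence x between copies) and Poisson(``L_a * indel_rate``) indels.
    ``revcomp_fraction`` of the copies may be planted reverse-complemented
    for strand-resolution experiments.
    """
    if N_a * L_a >= 0.5 * length:
        raise ValueError("N_a * L_a must be below half the genome length")
    rng = np.random.default_rng(seed)
    mother = _random_seq(rng, L_a, background_freq)
    n_subs = int(round(0.5 * x * L_a))
    copies, meta = [], []
    for _ in range(N_a):
        n_indels = int(rng.poisson(L_a * indel_rate))
        seq, applied = mutate_copy(mother, n_subs, n_indels, rng)
        strand = "+"
        if revcomp_fraction > 0 and rng.random() < revcomp_fraction:
            from .genome import COMPLEMENT
            seq = COMPLEMENT[seq[::-1]]
            strand = "-"
        copies.append(seq)
        meta.append((strand, n_subs, applied))
    genome_codes, intervals = _place_copies(length, copies, rng,
                                            background_freq)
    truth = PlantedTruth(
        mothers=[decode(mother)],
        copies=[PlantedCopy(start=s, end=e, family=1, strand=m[0],
                            n_subs=m[1], n_indels=m[2])
                for (s, e), m in zip(intervals, meta)],
        length=length, L_a=L_a, x=x, seed=seed)
    genome = from_records([(RECORD_NAME, decode(genome_codes))])
    return genome, truth


def make_two_family_genome(x_between: float, N: int = 250, L_a: int = 600,
                           length: int = 4_000_000, seed: int = 0,
                           background_freq=None,
                           ) -> tuple[GenomeIndex, PlantedTruth]:
    """Two families of N internally identical copies at mutual divergence x.

    Both mothers derive from a common ancestor, each receiving
    ``round(0.5 * x_between * L_a)`` substitutions, so the expected pairwise
    divergence between the families is ``x_between`` (up to coincident-site
    saturation).  Placement order is randomly interleaved.
    """
    if 2 * N * L_a >= 0.5 * length:
        raise ValueError("planted copies must occupy below half the genome")
    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, L_a, background_freq)
    n_subs = int(round(0.5 * x_between * L_a))
    mothers = [mutate_copy(ancestor, n_subs, 0, rng)[0] for _ in range(2)]
    labels = np.array([1] * N + [2] * N)
    rng.shuffle(labels)
    copies = [mothers[l - 1] for l in labels]
    genome_codes, intervals = _place_copies(length, copies, rng,
                                            background_freq)
    truth = PlantedTruth(
        mothers=[decode(m) for m in mothers],
        copies=[PlantedCopy(start=s, end=e, family=int(l), n_subs=n_subs)
                for (s, e), l in zip(intervals, labels)],
        length=length, L_a=L_a, x=x_between, seed=seed)
    genome = from_records([(RECORD_NAME, decode(genome_codes))])
    return genome, truth


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryMetrics:
    """Planted-truth scoring of a set of found repeat hits."""

    sensitivity: float
    fdr: float
    n_recovered: int
    n_copies: int
    n_hits: int
    purity: dict[int, float] = field(default_factory=dict)  # found family -> purity
    confusion: dict[tuple[int, int], int] = field(default_factory=dict)
    # (found family, true family) -> hit count


def _overlap(a, b, c, d) -> int:
    return max(0, min(b, d) - max(a, c) + 1)


def evaluate_recovery(hits, truth: PlantedTruth,
                      match_fraction: float = 0.5) -> RecoveryMetrics:
    """Score found hits against the planted truth.

    A planted copy counts as recovered when some hit overlaps it by more
    than ``match_fraction`` of the copy length; a hit is a false positive
    when no copy overlaps it by more than ``match_fraction`` of the hit
    length.  Purity of a found family is the largest fraction of its
    truth-matched hits tracing to a single mother.
    """
    hits = list(hits)
    recovered = np.zeros(len(truth.copies), dtype=bool)
    hit_matched = np.zeros(len(hits), dtype=bool)
    assignment: list[tuple[int, int]] = []  # (found family, true family)
    for hi, h in enumerate(hits):
        if getattr(h, "record", RECORD_NAME) != RECORD_NAME:
            continue
        best_ov, best_copy = 0, None
        for ci, c in enumerate(truth.copies):
            ov = _overlap(h.start, h.end, c.start, c.end)
            if ov > match_fraction * c.length:
                recovered[ci] = True
            if ov > best_ov:
                best_ov, best_copy = ov, c
        h_len = h.end - h.start + 1
        if best_copy is not None and best_ov > match_fraction * h_len:
            hit_matched[hi] = True
            assignment.append((h.family, best_copy.family))
    confusion: dict[tuple[int, int], int] = {}
    for key in assignment:
        confusion[key] = confusion.get(key, 0) + 1
    purity: dict[int, float] = {}
    for fam in sorted({f for f, _ in assignment}):
        counts = [c for (f, _), c in confusion.items() if f == fam]
        purity[fam] = max(counts) / sum(counts)
    n_hits = len(hits)
    fdr = float((~hit_matched).sum() / n_hits) if n_hits else 0.0
    return RecoveryMetrics(
        sensitivity=float(recovered.sum() / len(truth.copies))
        if truth.copies else 0.0,
        fdr=fdr, n_recovered=int(recovered.sum()),
        n_copies=len(truth.copies), n_hits=n_hits,
        purity=purity, confusion=confusion)
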