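"""Genome containers, coordinate bookkeeping, shuffling, masking and table I/O.

The discovery procedure works on a single concatenated sequence ``S`` of
length ``L_S`` obtained by merging all FASTA records in file order.  The
:class:`GenomeIndex` owns that concatenation, the per-record offsets needed to
translate hits back to record coordinates, the global base-frequency table
``f(k)`` used to build PWM background probabilities, and a boolean mask
channel marking bases already claimed by an accepted repeat family.

Coordinates are 1-based inclusive in every user-facing table (and in
:class:`GenomicInterval`); internal arrays and BED exports are 0-based
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

# Base codes follow the row-index convention of the dinucleotide PWM:
# a=0, t=1, c=2, g=3 (so that row = prev + 4*cur).  N and anything
# non-ACGT map to -1.
BASES = "atcg"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.upper())] = _i

#: complement in code space: a<->t, c<->g
COMPLEMENT = np.array([1, 0, 3, 2], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (a=0, t=1, c=2, g=3, other=-1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; -1 becomes ``N``."""
    lut = np.frombuffer(b"atcgN", dtype=np.uint8)
    return lut[np.where(codes < 0, 4, codes)].tobytes().decode("ascii")


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a named record."""

    record: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeIndex:
    """Concatenated genome with coordinate map, base frequencies and mask."""

    records: list[tuple[str, int]]
    codes: np.ndarray  # int8, length L_S
    offsets: np.ndarray  # int64 start of each record in the concatenation
    base_freq: np.ndarray  # f(k) for k in a,t,c,g over non-N bases
    mask: np.ndarray = field(default=None)  # bool, claimed bases

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(len(self.codes), dtype=bool)
        if len(self.mask) != len(self.codes):
            raise ValueError("mask length must equal sequence length")
        if sum(n for _, n in self.records) != len(self.codes):
            raise ValueError("record lengths do not sum to sequence length")

    # -- basic properties ---------------------------------------------------
    @property
    def length(self) -> int:
        """Total concatenated length ``L_S``."""
        return len(self.codes)

    @property
    def sequence(self) -> str:
        return decode(self.codes)

    # -- coordinate translation --------------------------------------------
    def to_record_coords(self, pos: int) -> tuple[str, int]:
        """Map a 1-based concatenated position to (record, 1-based position)."""
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside [1, {self.length}]")
        idx = int(np.searchsorted(self.offsets, pos - 1, side="right")) - 1
        return self.records[idx][0], pos - int(self.offsets[idx])

    def to_concat_coords(self, record: str, pos: int) -> int:
        """Map (record name, 1-based position) to a 1-based concatenated position."""
        for (name, n), off in zip(self.records, self.offsets):
            if name == record:
                if not 1 <= pos <= n:
                    raise ValueError(f"position {pos} outside record {name}")
                return int(off) + pos
        raise KeyError(f"unknown record {record!r}")

    def interval_to_concat(self, iv: GenomicInterval) -> tuple[int, int]:
        """Record interval -> 1-based inclusive concatenated (start, end)."""
        s = self.to_concat_coords(iv.record, iv.start)
        return s, s + iv.length - 1

    # -- derived genomes ----------------------------------------------------
    def copy(self) -> "GenomeIndex":
        return replace(self, codes=self.codes.copy(), mask=self.mask.copy())


def _base_frequencies(codes: np.ndarray) -> np.ndarray:
    counts = np.bincount(codes[codes >= 0], minlength=4).astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("genome contains no A/C/G/T bases")
    return counts / total


def from_records(named_seqs: list[tuple[str, str]]) -> GenomeIndex:
    """Build a :class:`GenomeIndex` from (name, sequence) pairs in order."""
    if not named_seqs:
        raise ValueError("no sequence records supplied")
    names = [n for n, _ in named_seqs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate record names in input")
    parts = [encode(s) for _, s in named_seqs]
    codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.int8)
    lengths = [len(p) for p in parts]
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(np.int64)
    return GenomeIndex(
        records=list(zip(names, lengths)),
        codes=codes,
        offsets=offsets,
        base_freq=_base_frequencies(codes),
    )


def load_genome(fasta_path) -> GenomeIndex:
    """Read a multi-record FASTA into a :class:`GenomeIndex`.

    Records are concatenated in file order; non-ACGTN characters are mapped
    to N.  Raises ``ValueError`` on an empty file or duplicate record names.
    """
    named = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")]
    return from_records(named)


def write_genome(genome: GenomeIndex, fasta_path) -> None:
    """Write the genome back out as uncompressed FASTA (one record per input)."""
    with open(fasta_path, "w") as fh:
        for (name, n), off in zip(genome.records, genome.offsets):
            fh.write(f">{name}\n")
            seq = decode(genome.codes[off : off + n]).upper()
            for i in range(0, n, 70):
                fh.write(seq[i : i + 70] + "\n")


def shuffle_genome(genome: GenomeIndex, seed: int) -> GenomeIndex:
    """Random permutation of the whole concatenation (exact base multiset).

    Record boundaries and names are kept so that coordinates remain valid;
    only the base order changes.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    shuffled = genome.codes[rng.permutation(genome.length)]
    return GenomeIndex(
        records=list(genome.records),
        codes=shuffled,
        offsets=genome.offsets.copy(),
        base_freq=genome.base_freq.copy(),
    )


def apply_mask(genome: GenomeIndex, intervals) -> GenomeIndex:
    """Return a genome with ``intervals`` (1-based concat (start, end) pairs or
    :class:`GenomicInterval`) added to the mask.  Idempotent."""
    out = genome.copy()
    for iv in intervals:
        if isinstance(iv, GenomicInterval):
            s, e = genome.interval_to_concat(iv)
        else:
            s, e = iv
        if not (1 <= s <= e <= genome.length):
            raise ValueError(f"interval ({s}, {e}) outside [1, {genome.length}]")
        out.mask[s - 1 : e] = True
    return out


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

REPEAT_COLUMNS = ["family", "record", "start", "end", "strand", "Z", "length"]


def hits_to_frame(hits) -> pd.DataFrame:
    """Convert an iterable of RepeatHit-like objects to the standard table."""
    rows = [
        {
            "family": h.family,
            "record": h.record,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "Z": h.Z,
            "length": h.end - h.start + 1,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=REPEAT_COLUMNS)


def write_repeat_table(hits, path) -> None:
    """Write hits as CSV with 1-based inclusive coordinates."""
    hits_to_frame(hits).to_csv(path, index=False)


def read_repeat_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REPEAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"repeat table missing columns: {sorted(missing)}")
    return df


def write_bed(hits, path) -> None:
    """BED6 export (0-based half-open: start-1, end)."""
    df = hits_to_frame(hits)
    bed = pd.DataFrame(
        {
            "chrom": df["record"],
            "start": df["start"] - 1,
            "end": df["end"],
            "name": df["family"],
            "score": df["Z"].round(3),
            "strand": df["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gff_genes(path, feature_type: str = "gene") -> list[GenomicInterval]:
    """Collect intervals of ``feature_type`` from a GFF3 file.

    Malformed lines are skipped with a logged warning count rather than
    aborting the run.
    """
    out: list[GenomicInterval] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                skipped += 1
                continue
            if parts[2] != feature_type:
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
                strand = parts[6] if parts[6] in "+-" else "+"
                out.append(GenomicInterval(parts[0], start, end, strand))
            except (ValueError, IndexError):
                skipped += 1
    if skipped:
        log.warning("skipped %d malformed GFF lines in %s", skipped, path)
    return out


def read_annotated_repeats(path) -> list[tuple[str, GenomicInterval]]:
    """Read an annotated-repeat table with columns class, chrom, start, end.

    Accepts CSV or TSV (sniffed from the header line).  Returns
    (class, interval) pairs; coordinates are taken as 1-based inclusive.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    required = ["class", "chrom", "start", "end"]
    if not all(c in cols for c in required):
        raise ValueError(f"annotated-repeat table needs columns {required}")
    return [
        (str(row[cols["class"]]),
         GenomicInterval(str(row[cols["chrom"]]), int(row[cols["start"]]),
                         int(row[cols["end"]])))
        for _, row in df.iterrows()
    ]
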