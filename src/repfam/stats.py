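"""Per-family consensus statistics and annotation-intersection analysis.

After discovery, every family member is re-aligned to the family profile and
a 4 x L base-count matrix is accumulated.  Column-wise standardised
deviations from the family-wide base composition give a chi-square-type
conservation statistic per column, normalised to an approximately standard
normal scale: ``X(j) = sqrt(2 chi(j)) - sqrt(2n - 1)`` with n = 3 degrees of
freedom.  Large X(j) marks conserved "islands" inside otherwise highly
diverged repeats.

Intersection analysis counts overlaps between repeat hits and annotation
features under strict more-than-half-length rules, and standardises the
class-by-family contingency matrix the same way the count matrices are
standardised elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .align import align_local
from .genome import BASES, COMPLEMENT, GenomeIndex
from .pwm import PWM, PWMConfig

SQRT5 = float(np.sqrt(5.0))  # sqrt(2n - 1) for n = 3


# ---------------------------------------------------------------------------
# Consensus profile
# ---------------------------------------------------------------------------

@dataclass
class ConsensusProfile:
    """4 x L count matrix of re-aligned members with conservation statistics."""

    M4: np.ndarray  # counts, rows a,t,c,g
    n_members: int = 0
    n_skipped: int = 0  # members that failed to re-align
    member_rows: list[str] = field(default_factory=list)  # logo-ready rows

    @property
    def L(self) -> int:
        return self.M4.shape[1]

    @property
    def N_j(self) -> np.ndarray:
        return self.M4.sum(axis=0)

    @property
    def y(self) -> np.ndarray:
        return self.M4.sum(axis=1)

    @property
    def p(self) -> np.ndarray:
        total = self.y.sum()
        return self.y / total if total > 0 else np.zeros(4)

    @property
    def w(self) -> np.ndarray:
        return column_deviation(self.M4)

    @property
    def chi(self) -> np.ndarray:
        return (self.w**2).sum(axis=0)

    @property
    def X(self) -> np.ndarray:
        return np.sqrt(2.0 * self.chi) - SQRT5

    @property
    def consensus(self) -> str:
        return symbolic_consensus(self.M4)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.M4.T, columns=list(BASES))
        df.insert(0, "column", np.arange(1, self.L + 1))
        df["N_j"] = self.N_j
        df["chi"] = self.chi
        df["X"] = self.X
        df["consensus"] = list(self.consensus)
        return df


def counts_from_trace(M4: np.ndarray, s1, s2) -> None:
    """Add one member's aligned pairs to the 4 x L count matrix in place.

    A position contributes only when both the base (s1) and the column (s2)
    are real; positions opposite a deletion on either side add nothing.
    """
    L = M4.shape[1]
    for base, col in zip(np.asarray(s1), np.asarray(s2)):
        if base < 0 or col < 1:
            continue
        if col > L:
            raise ValueError(f"column {col} outside [1, {L}]")
        M4[int(base), int(col) - 1] += 1


def _revcomp(codes: np.ndarray) -> np.ndarray:
    return COMPLEMENT[codes[::-1]]


def build_count_matrix(family, genome: GenomeIndex,
                       config: PWMConfig) -> ConsensusProfile:
    """Re-align every family member to the family profile and count bases.

    Hits on the '-' strand are reverse-complemented before alignment so that
    all members are counted against the same (direct) column frame.  Members
    whose re-alignment scores 0 are skipped and counted in ``n_skipped``.
    """
    pwm: PWM = family.pwm
    prof = ConsensusProfile(M4=np.zeros((4, pwm.L)))
    for hit in family.hits:
        cs = genome.to_concat_coords(hit.record, hit.start)
        seg = genome.codes[cs - 1 : cs - 1 + hit.length]
        if hit.strand == "-":
            seg = _revcomp(seg)
        tr = align_local(pwm, seg, config.gap_abs)
        if tr.k == 0:
            prof.n_skipped += 1
            continue
        counts_from_trace(prof.M4, tr.s1, tr.s2)
        prof.member_rows.append(_logo_row(tr, pwm.L))
        prof.n_members += 1
    return prof


def _logo_row(trace, L: int) -> str:
    """Length-L member row: base where aligned to a column, '-' elsewhere."""
    row = ["-"] * L
    for base, col in zip(trace.s1, trace.s2):
        if base >= 0 and col >= 1:
            row[int(col) - 1] = BASES[int(base)]
    return "".join(row)


def column_deviation(M4: np.ndarray) -> np.ndarray:
    """Standardised base deviations per column.

    ``w(i,j) = (M4(i,j) - N_j p(i)) / sqrt(N_j p(i) (1 - p(i)))`` with p(i)
    the family-wide base frequencies.  Rows with degenerate p (0 or 1), and
    columns with no observations, are set to 0.
    """
    M4 = np.asarray(M4, dtype=float)
    N_j = M4.sum(axis=0)
    y = M4.sum(axis=1)
    total = y.sum()
    w = np.zeros_like(M4)
    if total <= 0:
        return w
    p = y / total
    for i in range(4):
        if p[i] <= 0 or p[i] >= 1:
            continue
        ok = N_j > 0
        w[i, ok] = (M4[i, ok] - N_j[ok] * p[i]) / np.sqrt(
            N_j[ok] * p[i] * (1 - p[i]))
    return w


def column_statistic(w_column: np.ndarray, n: int = 3) -> float:
    """Normalised conservation statistic X = sqrt(2 chi) - sqrt(2n - 1)."""
    chi = float((np.asarray(w_column, dtype=float) ** 2).sum())
    return float(np.sqrt(2.0 * chi) - np.sqrt(2.0 * n - 1.0))


def symbolic_consensus(M4: np.ndarray) -> str:
    """Strict-majority consensus: base with count > N_j / 2, else '-'."""
    M4 = np.asarray(M4, dtype=float)
    out = []
    for j in range(M4.shape[1]):
        nj = M4[:, j].sum()
        if nj <= 0:
            out.append("-")
            continue
        i = int(M4[:, j].argmax())
        out.append(BASES[i] if M4[i, j] > nj / 2 else "-")
    return "".join(out)


def column_entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of one column's base distribution."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def max_column_entropy_bits(alphabet_size: int = 4) -> float:
    """Upper bound of the per-column entropy (2 bits for DNA)."""
    return float(np.log2(alphabet_size))


def write_member_alignment(profile: ConsensusProfile, path,
                           family_id: int = 1) -> None:
    """Logo-renderer-ready multi-FASTA of re-aligned member rows."""
    with open(path, "w") as fh:
        for i, row in enumerate(profile.member_rows, start=1):
            fh.write(f">family{family_id}_member{i}\n{row}\n")


# ---------------------------------------------------------------------------
# Annotation intersection
# ---------------------------------------------------------------------------

def _overlap(a_start, a_end, b_start, b_end) -> int:
    """Overlap length of two 1-based inclusive intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def intersect_features(hits, features, min_fraction: float = 0.5,
                       mode: str = "gene") -> list[tuple[int, int, int]]:
    """Report (hit index, feature index, overlap) pairs under the >50% rules.

    ``mode='gene'``: a pair qualifies when the overlap exceeds
    ``min_fraction`` of the repeat length OR of the feature length.
    ``mode='repeat'``: only the repeat-length rule applies (used against
    annotated-repeat tables).  Both rules are strict (>).  Many-to-many
    pairs are allowed.
    """
    if mode not in ("gene", "repeat"):
        raise ValueError("mode must be 'gene' or 'repeat'")
    trees: dict[str, IntervalTree] = {}
    for fi, feat in enumerate(features):
        iv = feat[1] if isinstance(feat, tuple) else feat
        trees.setdefault(iv.record, IntervalTree()).addi(iv.start, iv.end + 1,
                                                         (fi, iv))
    out = []
    for hi, hit in enumerate(hits):
        tree = trees.get(hit.record)
        if tree is None:
            continue
        for node in sorted(tree.overlap(hit.start, hit.end + 1)):
            fi, iv = node.data
            ov = _overlap(hit.start, hit.end, iv.start, iv.end)
            hit_len = hit.end - hit.start + 1
            qualifies = ov > min_fraction * hit_len
            if mode == "gene":
                qualifies = qualifies or ov > min_fraction * iv.length
            if qualifies:
                out.append((hi, fi, ov))
    return out


@dataclass
class ClassFamilyMatrix:
    """Annotation-class x repeat-family intersection counts, standardised."""

    V: pd.DataFrame  # rows: classes, columns: families

    @property
    def n(self) -> float:
        return float(self.V.values.sum())

    @property
    def v_prime(self) -> pd.DataFrame:
        V = self.V.values.astype(float)
        n = V.sum()
        out = np.zeros_like(V)
        if n > 0:
            p = np.outer(V.sum(axis=1), V.sum(axis=0)) / (n * n)
            denom_sq = n * p * (1 - p)
            ok = denom_sq > 0
            out[ok] = (V[ok] - n * p[ok]) / np.sqrt(denom_sq[ok])
        return pd.DataFrame(out, index=self.V.index, columns=self.V.columns)

    def flagged(self, threshold: float = 3.0) -> pd.DataFrame:
        """Sign flags at |v'| > threshold ('+' enriched, '-' depleted)."""
        vp = self.v_prime
        return vp.map(lambda v: "+" if v > threshold
                      else ("-" if v < -threshold else ""))


def class_family_enrichment(pairs) -> ClassFamilyMatrix:
    """Build the V matrix from (class label, family id) pairs and standardise.

    ``v'(i,j) = (V(i,j) - n p(i,j)) / sqrt(n p(i,j) (1 - p(i,j)))`` with
    p(i,j) the product of the normalised margins; degenerate cells are 0.
    """
    if not pairs:
        return ClassFamilyMatrix(V=pd.DataFrame())
    df = pd.DataFrame(pairs, columns=["cls", "family"])
    V = pd.crosstab(df["cls"], df["family"])
    V.index.name = "class"
    return ClassFamilyMatrix(V=V)


def length_histogram(hits, bins=20) -> tuple[pd.DataFrame, dict]:
    """Length distribution of hits plus min/max/mean summary."""
    lengths = np.array([h.end - h.start + 1 for h in hits])
    if len(lengths) == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"]), {}
    counts, edges = np.histogram(lengths, bins=bins)
    table = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                          "count": counts})
    summary = {"min": int(lengths.min()), "max": int(lengths.max()),
               "mean": float(lengths.mean()), "n": int(len(lengths))}
    return table, summary
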