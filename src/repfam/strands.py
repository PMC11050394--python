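"""Both-strand family search, overlap resolution and FDR calibration.

Discovery refines profiles on one strand only, so a family's direct and
reverse-complement copies surface separately.  The accepted profile and its
inversion are both scanned over the genome; inverted-profile hits are
reported on the '-' strand with forward-reference coordinates.  A per-family
significance threshold ``Z0`` is then chosen as the smallest grid value whose
empirical false discovery rate - hit count on a shuffled genome over total
hit count - stays within the configured bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import GenomeIndex
from .pwm import PWM, PWMConfig, invert_pwm
from .scan import calibrate_null, local_maxima, scan, traces_at, z_transform

DEFAULT_Z0_GRID = tuple(5.0 + 0.5 * i for i in range(11))  # 5.0 .. 10.0


@dataclass
class RepeatHit:
    """One genomic repeat copy (1-based inclusive record coordinates)."""

    record: str
    start: int
    end: int
    strand: str
    Z: float
    family: int
    source: str = "direct"  # direct | inverted
    concat_start: int = 0  # 1-based concatenated coordinates (internal)
    concat_end: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FdrTable:
    """Hit counts on the real and shuffled genomes along the Z0 grid."""

    grid: np.ndarray
    TP: np.ndarray  # hit count in the real genome at each Z0
    FP: np.ndarray  # hit count in the shuffled genome
    Z0_selected: float
    attained: bool  # whether any grid point met the FDR bound

    @property
    def FDR(self) -> np.ndarray:
        total = self.TP + self.FP
        with np.errstate(invalid="ignore", divide="ignore"):
            fdr = np.where(total > 0, self.FP / total, 0.0)
        return fdr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"Z0": self.grid, "TP": self.TP, "FP": self.FP,
                             "FDR": self.FDR})


def fdr_value(TP: float, FP: float) -> float:
    """FDR = FP / (FP + TP); 0 when there are no hits at all."""
    total = TP + FP
    return FP / total if total > 0 else 0.0


def _hits_from_profile(genome: GenomeIndex, pwm: PWM, config: PWMConfig,
                       profile, maxima, family: int, strand: str,
                       source: str) -> list[RepeatHit]:
    hits = []
    traces = traces_at(genome, pwm, config, profile, maxima)
    for t, tr in zip(maxima, traces):
        cs, ce = tr.genomic_span
        rec, rstart = genome.to_record_coords(cs)
        hits.append(RepeatHit(record=rec, start=rstart,
                              end=rstart + (ce - cs), strand=strand,
                              Z=float(profile.Z[t]), family=family,
                              source=source, concat_start=cs, concat_end=ce))
    return hits


def search_family(genome: GenomeIndex, shuffled: GenomeIndex, pwm: PWM,
                  config: PWMConfig, family: int, Z0: float,
                  count_only: bool = False):
    """Scan the genome with a family profile and its inversion.

    Returns (direct hits, inverted hits) above ``Z0``, or (in
    ``count_only`` mode) per-strand maxima Z values on both the real and
    shuffled genome for FDR calibration.
    """
    inv = invert_pwm(pwm)
    out = {}
    for label, mat in (("direct", pwm), ("inverted", inv)):
        null = calibrate_null(shuffled, mat, config)
        real = z_transform(scan(genome, mat, config), null)
        rand = z_transform(scan(shuffled, mat, config), null)
        out[label] = (real, rand, null)

    if count_only:
        return out

    hits: list[RepeatHit] = []
    for label, strand in (("direct", "+"), ("inverted", "-")):
        real, _, _ = out[label]
        maxima = local_maxima(real, Z0, config.maxima_halfwidth)
        mat = pwm if label == "direct" else inv
        hits.extend(_hits_from_profile(genome, mat, config, real, maxima,
                                       family, strand, label))
    direct = [h for h in hits if h.source == "direct"]
    inverted = [h for h in hits if h.source == "inverted"]
    return direct, inverted


def maxima_counts(profile, grid, halfwidth: int) -> np.ndarray:
    """Number of significant local maxima at each Z0 of the grid."""
    return np.array([len(local_maxima(profile, z0, halfwidth)) for z0 in grid],
                    dtype=np.int64)


def calibrate_fdr(real_counts: np.ndarray, shuffled_counts: np.ndarray,
                  grid=DEFAULT_Z0_GRID, fdr_max: float = 0.04) -> FdrTable:
    """Pick the smallest grid Z0 with FDR <= fdr_max.

    When no grid value attains the bound the largest grid value is used and
    the table is flagged (``attained=False``).
    """
    grid = np.asarray(grid, dtype=float)
    TP = np.asarray(real_counts, dtype=np.int64)
    FP = np.asarray(shuffled_counts, dtype=np.int64)
    if not (len(grid) == len(TP) == len(FP)):
        raise ValueError("grid and count vectors must have equal length")
    fdr = np.array([fdr_value(tp, fp) for tp, fp in zip(TP, FP)])
    ok = np.nonzero(fdr <= fdr_max)[0]
    if len(ok):
        return FdrTable(grid, TP, FP, float(grid[ok[0]]), True)
    return FdrTable(grid, TP, FP, float(grid[-1]), False)


def resolve_overlaps(hits: list[RepeatHit], min_shared: int = 50) -> list[RepeatHit]:
    """Greedy max-Z deduplication of hits sharing more than ``min_shared`` bases.

    Applied separately per strand class (direct and inverted hit sets are
    resolved independently, mirroring the separate treatment of G and
    G^inver).  Within a class, hits are taken in decreasing Z (ties: earlier
    start, then lower family id); a hit is dropped when it shares more than
    ``min_shared`` bases with an already-kept hit on the same reference.
    """
    kept: list[RepeatHit] = []
    for source in ("direct", "inverted"):
        group = [h for h in hits if h.source == source]
        order = sorted(group, key=lambda h: (-h.Z, h.concat_start, h.family))
        tree = IntervalTree()
        for h in order:
            # half-open interval in concatenated coordinates
            s, e = h.concat_start, h.concat_end + 1
            shared = 0
            for iv in tree.overlap(s, e):
                shared = max(shared, min(e, iv.end) - max(s, iv.begin))
            if shared > min_shared:
                continue
            tree.addi(s, e, h)
            kept.append(h)
    kept.sort(key=lambda h: (h.concat_start, h.strand))
    return kept
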