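"""The iterative refinement loop that turns random matrices into repeat families.

Each chain starts from a random normalised PWM and alternates: scan the
genome -> keep significant local maxima -> re-estimate the dinucleotide
count matrix from their alignments -> standardise -> renormalise.  The first
iteration uses a permissive threshold (Z0 = 3) so that weak, accidental
resonances between the random matrix and a repeat family can seed the chain;
later iterations use Z0 = 5.  A chain's best iteration is the one (with
i > 8, to skip early transients) with the most surviving maxima; the best
chain over all random starts defines a candidate family, accepted when its
member count exceeds ``N_min``.  Accepted members are masked and the whole
sweep repeats until no further family passes the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeIndex, apply_mask, shuffle_genome
from .pwm import (PWM, PWMConfig, accumulate_MAT, background_p1, random_pwm,
                  standardize_M, transform_pwm)
from .scan import calibrate_null, local_maxima, scan, traces_at, z_transform
from .strands import FdrTable, RepeatHit

log = logging.getLogger(__name__)


@dataclass
class IterationRecord:
    """Book-keeping for one refinement iteration of one chain."""

    i: int
    N_z: int
    maxima: np.ndarray  # profile indices t of surviving maxima


@dataclass
class ChainResult:
    """Outcome of refining a single random starting matrix."""

    matrix_index: int
    records: list[IterationRecord]
    best_i: int | None = None  # i_max (restricted to i > i_min)
    best_N: int = 0
    best_pwm: PWM | None = None
    best_maxima: np.ndarray | None = None
    best_traces: list | None = None
    best_Z: np.ndarray | None = None

    @property
    def n_z_series(self) -> list[int]:
        return [r.N_z for r in self.records]


@dataclass
class RepeatFamily:
    """An accepted family: its profile, discovery members and statistics."""

    family: int
    pwm: PWM
    N_max: int
    i_max: int
    matrix_index: int
    hits: list[RepeatHit] = field(default_factory=list)
    Z0_family: float | None = None
    fdr_table: FdrTable | None = None
    n_z_series: list[int] = field(default_factory=list)


def family_size_zscore(n_members: float, null_mean: float = 122.0,
                       null_sd: float = 12.0) -> float:
    """Deviation of a family size from the shuffled-genome expectation.

    The acceptance threshold for ``N_min`` is chosen so that this z-score is
    large (> 10): family sizes reachable by chance alone must be far below
    the acceptance bar.
    """
    return (n_members - null_mean) / null_sd


def best_iteration(n_z_series, i_min: int = 8) -> tuple[int | None, int]:
    """(i_max, N_max) over iterations with i > i_min; earliest i wins ties.

    Returns (None, 0) when no qualifying iteration has any maxima.
    """
    best_i, best_n = None, 0
    for i, n in enumerate(n_z_series, start=1):
        if i > i_min and n > best_n:
            best_i, best_n = i, n
    return best_i, best_n


def refine_matrix(genome: GenomeIndex, mt0: PWM, shuffled: GenomeIndex,
                  config: PWMConfig, matrix_index: int = 0) -> ChainResult:
    """Run the 20-iteration (by default) refinement of one starting matrix.

    Iteration thresholds follow ``config.z0_for_iteration``: ``Z0_first``
    (3.0) on the first pass, then ``Z0_iter`` (5.0); scaled-down profiles
    ramp to a stricter ``Z0_final`` after nucleation so that a locked family
    sheds cross-family and null members.  The chain stops early when an
    iteration
    yields no maxima or a degenerate count matrix.  The snapshot of the best
    qualifying iteration (i > i_min, largest N_z, earliest such i) is kept:
    its matrix, maxima and alignment traces.
    """
    chain = ChainResult(matrix_index=matrix_index, records=[])
    mt = mt0
    null = None
    for i in range(1, config.n_iterations + 1):
        z0 = config.z0_for_iteration(i)
        if null is None or config.recalibrate_each_iteration:
            null = calibrate_null(shuffled, mt, config)
        profile = z_transform(scan(genome, mt, config), null)
        maxima = local_maxima(profile, z0, config.maxima_halfwidth)
        chain.records.append(IterationRecord(i=i, N_z=len(maxima),
                                             maxima=maxima))
        if len(maxima) == 0:
            log.debug("chain %d: no maxima at iteration %d", matrix_index, i)
            break
        traces = traces_at(genome, mt, config, profile, maxima)
        if i > config.i_min and len(maxima) > chain.best_N:
            chain.best_i = i
            chain.best_N = len(maxima)
            chain.best_pwm = mt
            chain.best_maxima = maxima
            chain.best_traces = traces
            chain.best_Z = profile.Z[maxima].copy()
        if i == config.n_iterations:
            break
        freq = accumulate_MAT(traces, config.L)
        try:
            M = standardize_M(freq)
            mt = transform_pwm(M, mt.p1, config.R0_sq, config.K0)
        except ValueError:
            log.debug("chain %d: degenerate matrix at iteration %d",
                      matrix_index, i)
            break
    return chain


def select_best(chains: list[ChainResult]) -> ChainResult | None:
    """Best chain by N_z(i_max); ties go to the lowest matrix index."""
    best = None
    for chain in chains:
        if chain.best_i is None:
            continue
        if best is None or chain.best_N > best.best_N:
            best = chain
    return best


def _family_from_chain(genome: GenomeIndex, chain: ChainResult,
                       family_id: int) -> RepeatFamily:
    hits = []
    for tr, z in zip(chain.best_traces, chain.best_Z):
        cs, ce = tr.genomic_span
        rec, rstart = genome.to_record_coords(cs)
        hits.append(RepeatHit(record=rec, start=rstart, end=rstart + (ce - cs),
                              strand="+", Z=float(z), family=family_id,
                              source="direct", concat_start=cs,
                              concat_end=ce))
    return RepeatFamily(family=family_id, pwm=chain.best_pwm,
                        N_max=chain.best_N, i_max=chain.best_i,
                        matrix_index=chain.matrix_index, hits=hits,
                        n_z_series=chain.n_z_series)


def run_matrix_sweep(genome: GenomeIndex, shuffled: GenomeIndex,
                     config: PWMConfig, seed: int,
                     round_index: int) -> ChainResult | None:
    """Refine ``n_random_matrices`` random starts and pick the best chain."""
    p1 = background_p1(genome.base_freq)
    chains = []
    for m in range(config.n_random_matrices):
        rng = np.random.default_rng([seed, round_index, m])
        raw = random_pwm(config, rng)
        mt0 = transform_pwm(raw, p1, config.R0_sq, config.K0)
        chain = refine_matrix(genome, mt0, shuffled, config, matrix_index=m)
        log.info("round %d matrix %d: N_z series %s", round_index, m,
                 chain.n_z_series)
        chains.append(chain)
    return select_best(chains)


def discover_families(genome: GenomeIndex, config: PWMConfig,
                      seed: int | None = None,
                      shuffled: GenomeIndex | None = None,
                      max_families: int | None = None) -> list[RepeatFamily]:
    """Full discovery: repeat matrix sweeps, accept and mask families.

    Stops when the best candidate of a sweep has no more than ``N_min``
    members (or after ``max_families`` acceptances).  Accepted families'
    aligned spans are masked so later sweeps cannot re-claim them, which
    makes the discovered families pairwise disjoint on the genome.
    """
    if seed is None:
        seed = config.seed
    if shuffled is None:
        shuffled = shuffle_genome(genome, seed=(seed * 1_000_003 + 7) % (2**31))
    work = genome.copy()
    families: list[RepeatFamily] = []
    round_index = 0
    while True:
        round_index += 1
        best = run_matrix_sweep(work, shuffled, config, seed, round_index)
        if best is None or best.best_N <= config.N_min:
            log.info("round %d: best N_max %s <= N_min %d, stopping",
                     round_index, best.best_N if best else None, config.N_min)
            break
        family = _family_from_chain(work, best, family_id=len(families) + 1)
        families.append(family)
        spans = [(h.concat_start, h.concat_end) for h in family.hits]
        work = apply_mask(work, spans)
        log.info("accepted family %d: N_max=%d i_max=%d matrix=%d",
                 family.family, family.N_max, family.i_max,
                 family.matrix_index)
        if max_families is not None and len(families) >= max_families:
            break
    return families
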