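"""Frozen planted-truth benchmark designs.

These are the scaled study designs used by both the test suite and the
reproduction script: a recovery-versus-length experiment (with a
divergence-shifted variant) and a two-family resolution experiment.
Problem sizes and the scale-adapted thresholds are discussed in
docs/methods.md; they were fixed once from the measured desk-scale null and
nucleation behaviour and are not tuning knobs.
"""

from __future__ import annotations

from .model import RepeatDiscovery, RepeatDiscoveryResults
from .pwm import PWMConfig
from .simulate import (RecoveryMetrics, make_planted_genome,
                       make_two_family_genome)


def fig6_config(**overrides) -> PWMConfig:
    """Desk profile of the recovery-versus-length experiment."""
    params = dict(L=150, window=170, maxima_halfwidth=10, n_iterations=12,
                  null_windows=1500, N_min=150)
    params.update(overrides)
    return PWMConfig.desk(**params)


def length_transition_run(L_a: int, x: float, seed: int,
                          N_a: int = 300, length: int = 100_000,
                          ) -> RecoveryMetrics:
    """Discovery on a genome with N_a planted copies of length L_a.

    300 copies in 100 kb with a 150-column profile: full-profile-length
    members (L_a = 150) are recovered almost completely, members below
    ~1/6 of the profile length not at all, with the transition in between;
    raising the divergence x moves the boundary past the full length.
    """
    genome, truth = make_planted_genome(length=length, L_a=L_a, N_a=N_a,
                                        x=x, seed=seed + 20)
    results = RepeatDiscovery(genome, fig6_config()).fit(seed=seed)
    return results.evaluate(truth)


def two_family_config(**overrides) -> PWMConfig:
    return fig6_config(n_iterations=10, n_random_matrices=2, **overrides)


def two_family_run(x_between: float, seed: int, N: int = 200,
                   L_a: int = 150, length: int = 300_000,
                   ) -> tuple[RepeatDiscoveryResults, RecoveryMetrics]:
    """Two families of N identical copies at mutual divergence ``x_between``.

    At saturated mutual divergence the procedure ends with mother-pure
    families (a first mixed profile may precede them: with both families at
    equal abundance the first sweep can superpose the two patterns in one
    16-row matrix; the masked remnants then nucleate one family each).  At
    low mutual divergence every family blends the two mothers - they are a
    single family to the method.
    """
    genome, truth = make_two_family_genome(x_between=x_between, N=N,
                                           L_a=L_a, length=length,
                                           seed=seed + 30)
    results = RepeatDiscovery(genome, two_family_config()).fit(seed=seed)
    return results, results.evaluate(truth)


def per_mother_purity(results: RepeatDiscoveryResults,
                      metrics: RecoveryMetrics) -> dict[int, float]:
    """Best purity over found families majority-assigned to each mother."""
    best: dict[int, float] = {}
    for fam, purity in metrics.purity.items():
        counts = {m: c for (f, m), c in metrics.confusion.items() if f == fam}
        if not counts:
            continue
        mother = max(counts, key=counts.get)
        best[mother] = max(best.get(mother, 0.0), purity)
    return best


def random_genome_run(seed: int, length: int = 100_000
                      ) -> RepeatDiscoveryResults:
    """Discovery on a pure random genome: the expected family count is 0."""
    import numpy as np

    from .genome import from_records, decode
    from .simulate import _random_seq

    rng = np.random.default_rng(seed + 40)
    genome = from_records([("r", decode(_random_seq(rng, length)))])
    return RepeatDiscovery(genome, fig6_config()).fit(seed=seed,
                                                      search_strands=False)
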