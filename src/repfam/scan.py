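"""Sliding-window profile scan, null calibration and local-maxima extraction.

The profile is slid along the concatenated genome with a fixed stride; each
window yields the local-alignment score ``F(t)`` (``t = int(x/step) + 1`` for
window start x).  Statistical significance is measured against a randomly
shuffled genome of identical base composition: ``Z(t) = (F(t) - Fbar) /
sigma_F`` with ``Fbar``/``sigma_F`` estimated from the null scan.  Candidate
repeat loci are profile points that dominate their +/-65-step neighbourhood
and exceed the Z threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .align import _score_window, align_local, AlignmentTrace
from .genome import GenomeIndex
from .pwm import PWM, PWMConfig

FLAG_OK = 0
FLAG_MASKED = 1
FLAG_N = 2


@dataclass
class ScanProfile:
    """Window scores for one (genome, PWM) pair."""

    F: np.ndarray  # score per window
    coords: np.ndarray  # 1-based window start x per t
    flags: np.ndarray  # FLAG_* per window
    step: int
    window: int
    Z: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.F)


@dataclass
class NullCalibration:
    """Mean and spread of window scores on the shuffled genome."""

    F_mean: float
    F_sd: float
    n_windows: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.F_sd > 0:
            raise ValueError("degenerate null profile: sigma_F must be > 0")


def window_starts(L_S: int, window: int, step: int) -> np.ndarray:
    """1-based start coordinates of all full windows."""
    if L_S < window:
        raise ValueError(f"genome length {L_S} shorter than window {window}")
    n = (L_S - window) // step + 1
    return 1 + step * np.arange(n, dtype=np.int64)


@njit(cache=True)
def _scan_loop(codes, mask, starts, window, weights, g, max_n):  # pragma: no cover
    n = starts.shape[0]
    F = np.zeros(n)
    flags = np.zeros(n, dtype=np.int8)
    for t in range(n):
        x0 = starts[t] - 1
        win = codes[x0 : x0 + window]
        masked = False
        for b in range(window):
            if mask[x0 + b]:
                masked = True
                break
        if masked:
            flags[t] = 1
            continue
        n_count = 0
        for b in range(window):
            if win[b] < 0:
                n_count += 1
        if n_count > max_n:
            flags[t] = 2
            continue
        F[t] = _score_window(win, weights, g)
    return F, flags


def scan(genome: GenomeIndex, pwm: PWM, config: PWMConfig,
         starts: np.ndarray | None = None) -> ScanProfile:
    """Score every window of the genome against the profile.

    Windows overlapping masked bases, or containing more than
    ``max_n_fraction`` N bases, are flagged and left at F = 0 (their Z is
    forced to 0 downstream, so they can never seed or join a family).
    """
    if starts is None:
        starts = window_starts(genome.length, config.window, config.step)
    F, flags = _scan_loop(
        genome.codes, genome.mask, np.asarray(starts, dtype=np.int64),
        config.window, pwm.weights, float(config.gap_abs),
        int(config.max_n_fraction * config.window),
    )
    return ScanProfile(F=F, coords=np.asarray(starts, dtype=np.int64),
                       flags=flags, step=config.step, window=config.window)


def calibrate_null(shuffled: GenomeIndex, pwm: PWM, config: PWMConfig,
                   seed: int | None = None) -> NullCalibration:
    """Estimate Fbar and sigma_F on a shuffled genome.

    All windows are used when there are fewer than ``config.null_windows``;
    otherwise a seeded uniform subsample of that size keeps the calibration
    cost bounded (Fbar and sigma_F are global scalars, well estimated from a
    subsample).
    """
    starts = window_starts(shuffled.length, config.window, config.step)
    if len(starts) > config.null_windows:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        starts = np.sort(rng.choice(starts, size=config.null_windows,
                                    replace=False))
    profile = scan(shuffled, pwm, config, starts=starts)
    ok = profile.flags == FLAG_OK
    scores = profile.F[ok]
    if len(scores) < 2:
        raise ValueError("not enough usable null windows for calibration")
    sd = float(scores.std(ddof=1))
    if sd <= 0:
        raise ValueError("degenerate null profile: sigma_F is zero")
    return NullCalibration(F_mean=float(scores.mean()), F_sd=sd,
                           n_windows=int(ok.sum()), seed=seed)


def z_transform(profile: ScanProfile, null: NullCalibration) -> ScanProfile:
    """Standardise F(t) by the null; flagged windows get Z = 0."""
    Z = (profile.F - null.F_mean) / null.F_sd
    Z[profile.flags != FLAG_OK] = 0.0
    profile.Z = Z
    return profile


def local_maxima(profile: ScanProfile, Z0: float,
                 halfwidth: int = 65) -> np.ndarray:
    """Indices t (0-based into the profile) of significant local maxima.

    A point qualifies when F(t-i) <= F(t) >= F(t+i) for all i in
    [1, halfwidth] and Z(t) > Z0.  Plateaus report their leftmost point only
    (strict domination over the left neighbourhood); missing neighbours at
    the profile boundary cannot veto a maximum.
    """
    if profile.Z is None:
        raise ValueError("profile has no Z values; run z_transform first")
    F = profile.F
    n = len(F)
    out = []
    cand = np.nonzero(profile.Z > Z0)[0]
    for t in cand:
        lo = max(0, t - halfwidth)
        hi = min(n, t + halfwidth + 1)
        if t > lo and F[lo:t].max() >= F[t]:
            continue
        if hi > t + 1 and F[t + 1 : hi].max() > F[t]:
            continue
        out.append(t)
    return np.asarray(out, dtype=np.int64)


def traces_at(genome: GenomeIndex, pwm: PWM, config: PWMConfig,
              profile: ScanProfile, maxima: np.ndarray) -> list[AlignmentTrace]:
    """Re-align the windows at the given maxima with full traceback."""
    traces = []
    for t in maxima:
        x = int(profile.coords[t])
        win = genome.codes[x - 1 : x - 1 + config.window]
        tr = align_local(pwm, win, config.gap_abs, window_offset=x)
        if tr.k:
            traces.append(tr)
    return traces


def dump_profile(profile: ScanProfile, path) -> None:
    """TSV dump (t, x, F, Z) for plotting."""
    import pandas as pd

    pd.DataFrame(
        {
            "t": np.arange(1, len(profile) + 1),
            "x": profile.coords,
            "F": profile.F,
            "Z": profile.Z if profile.Z is not None else np.nan,
        }
    ).to_csv(path, sep="\t", index=False)
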