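"""Dinucleotide position weight matrices: creation, normalisation, inversion.

A family profile is a 16-row x L-column weight matrix.  Rows index ordered
dinucleotides (previous base, current base) through the map a=1, t=2, c=3,
g=4 and row ``n = let(prev) + 4*(let(cur) - 1)``; in 0-based code space
(a=0, t=1, c=2, g=3) this is simply ``row = prev + 4*cur``.  Scoring a base
together with its left neighbour lets the profile capture neighbouring-base
correlation, which is what allows family members with very low pairwise
sequence identity (divergence x > 1) to still be recognised.

Every matrix used for scanning is normalised so that, under the background
dinucleotide measure ``p1(i) * p2(j)`` (``p1(i) = f(k) f(l)`` from the genome
base frequencies, ``p2(j) = 1/L``):

* the weighted mean cell value equals ``K0`` (default -1.0), and
* the summed squared deviation about ``K0``, ``sum (m - K0)^2``, equals
  ``R0^2`` (default ``300 * L``, a fixed variance budget of 300 per column).

Under this budget the per-column score contrast, ``sqrt(R0^2 / L)``, is
independent of the profile length, so a family member's expected score
advantage per aligned position does not shrink as profiles grow; ``K0 = -1``
tilts random extension slightly negative against that contrast, which
controls the length of spurious local alignments while leaving genuinely
profile-like segments with a positive expected drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genome import COMPLEMENT

N_ROWS = 16


def dinucleotide_row(prev_code: int, cur_code: int) -> int:
    """0-based row index of the ordered dinucleotide (prev, cur)."""
    return int(prev_code) + 4 * int(cur_code)


def background_p1(base_freq: np.ndarray) -> np.ndarray:
    """Background dinucleotide probabilities p1(n) = f(prev) * f(cur)."""
    f = np.asarray(base_freq, dtype=float)
    prev = np.arange(N_ROWS) % 4
    cur = np.arange(N_ROWS) // 4
    return f[prev] * f[cur]


@dataclass
class PWMConfig:
    """All tunables of the discovery procedure.

    Defaults are the full-genome operating point: 600-column profiles scanned
    in 650-base windows every 10 bases, 50 random seed matrices refined for 20
    iterations each, and a family accepted only when it has more than
    ``N_min = 300`` members.  ``desk()`` returns a scaled-down profile for
    interactive work and continuous testing.
    """

    L: int = 600
    window: int = 650
    step: int = 10
    K0: float = -1.0
    R0_sq: float | None = None  # defaults to 300 * L
    Z0_first: float = 3.0
    Z0_iter: float = 5.0
    Z0_final: float | None = None  # consolidation threshold (default Z0_iter)
    ramp_iterations: int = 5  # iterations 2..1+ramp use Z0_iter, then Z0_final
    maxima_halfwidth: int = 65
    n_iterations: int = 20
    n_random_matrices: int = 50
    i_min: int = 8  # best iteration restricted to i > i_min
    N_min: int = 300  # family accepted when N_max > N_min
    fdr_max: float = 0.04
    gap_penalty: float = 2.0  # in units of the per-column score scale
    null_windows: int = 100_000  # null calibration subsample cap
    recalibrate_each_iteration: bool = True
    max_n_fraction: float = 0.10  # windows with more N than this are skipped
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.window < self.L:
            raise ValueError("window must be >= L")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.R0_sq is None:
            self.R0_sq = 300.0 * self.L
        if self.R0_sq <= 0:
            raise ValueError("R0_sq must be positive")
        if self.Z0_final is None:
            self.Z0_final = self.Z0_iter

    def z0_for_iteration(self, i: int) -> float:
        """Significance threshold schedule of the refinement loop.

        Iteration 1 uses the permissive seeding threshold, iterations up to
        ``1 + ramp_iterations`` the nucleation threshold, and later
        (consolidation) iterations ``Z0_final``.  With the full-scale
        defaults the schedule is the flat 3.0 then 5.0.
        """
        if i <= 1:
            return self.Z0_first
        if i <= 1 + self.ramp_iterations:
            return self.Z0_iter
        return self.Z0_final

    @property
    def score_scale(self) -> float:
        """Per-column score contrast sqrt(R0^2 / L)."""
        return float(np.sqrt(self.R0_sq / self.L))

    @property
    def gap_abs(self) -> float:
        """Gap cost per symbol in score units (gap_penalty * score_scale)."""
        return self.gap_penalty * self.score_scale

    @classmethod
    def desk(cls, **overrides) -> "PWMConfig":
        """Scaled-down configuration for desk-size experiments."""
        params = dict(
            L=100,
            window=120,
            step=10,
            n_random_matrices=3,
            n_iterations=12,
            N_min=150,
            null_windows=1500,
            maxima_halfwidth=12,  # one window length, as at full scale
            # seed/refinement thresholds track the smaller window count:
            # the full-scale 3.0/5.0 quantiles leave too few alignments on a
            # desk-size genome for the count matrix to average over
            Z0_first=1.5,
            Z0_iter=2.5,
            # consolidation at the full-scale threshold: once a family has
            # nucleated its members sit far above 5, while cross-family and
            # null windows fall back below it
            Z0_final=5.0,
        )
        params.update(overrides)
        return cls(**params)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PWM:
    """Normalised 16 x L weight matrix with its background probabilities."""

    weights: np.ndarray  # (16, L)
    p1: np.ndarray  # (16,)
    L: int = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        if self.weights.shape[0] != N_ROWS:
            raise ValueError("weight matrix must have 16 rows")
        if not np.isclose(self.p1.sum(), 1.0, atol=1e-9):
            raise ValueError("p1 must sum to 1")
        self.L = self.weights.shape[1]

    @property
    def p2(self) -> float:
        return 1.0 / self.L

    def weighted_mean(self) -> float:
        """K = sum m(i,j) p1(i) p2(j)."""
        return float(self.p1 @ self.weights.mean(axis=1))

    def centered_norm_sq(self, K0: float | None = None) -> float:
        """Summed squared deviation about K0 (default: the weighted mean)."""
        if K0 is None:
            K0 = self.weighted_mean()
        return float(((self.weights - K0) ** 2).sum())


def random_pwm(config: PWMConfig, rng: np.random.Generator) -> np.ndarray:
    """Raw 16 x L matrix with i.i.d. uniform entries on [-10, 10]."""
    return rng.uniform(-10.0, 10.0, size=(N_ROWS, config.L))


def transform_pwm(raw: np.ndarray, p1: np.ndarray,
                  R0_sq: float, K0: float) -> PWM:
    """Affine-normalise a raw matrix to the (K0, R0^2) constraints.

    ``m' = K0 + alpha * (m - Kbar)`` with ``Kbar`` the background-weighted
    mean of ``m`` and ``alpha = sqrt(R0^2 / sum (m - Kbar)^2)``.  The result
    has weighted mean exactly K0 and centered norm exactly R0^2; a matrix
    already satisfying both constraints is a fixed point, and the map is
    idempotent.  A constant matrix has no deviation to scale and raises
    ``ValueError``.
    """
    raw = np.asarray(raw, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    L = raw.shape[1]
    kbar = float(p1 @ raw.mean(axis=1))
    dev = raw - kbar
    ss = float((dev**2).sum())
    if ss <= 0 or not np.isfinite(ss):
        raise ValueError("degenerate (constant) matrix cannot be normalised")
    alpha = np.sqrt(R0_sq / ss)
    return PWM(weights=K0 + alpha * dev, p1=p1)


# row -> reverse-complement row: (prev, cur) -> (comp(cur), comp(prev))
_INV_ROW = np.empty(N_ROWS, dtype=np.int64)
for _r in range(N_ROWS):
    _p, _c = _r % 4, _r // 4
    _INV_ROW[int(COMPLEMENT[_c]) + 4 * int(COMPLEMENT[_p])] = _r


def invert_pwm(pwm: PWM) -> PWM:
    """Profile for the reverse-complement strand.

    Columns are reversed and each dinucleotide row (k, l) is moved to the row
    of (comp(l), comp(k)); the background p1 is remapped the same way, so its
    total mass is conserved.  The operation is an involution.
    """
    w = pwm.weights[_INV_ROW][:, ::-1].copy()
    p1 = pwm.p1[_INV_ROW].copy()
    return PWM(weights=w, p1=p1)


@dataclass
class FrequencyMatrix:
    """16 x L alignment counts MAT with its margins."""

    MAT: np.ndarray  # (16, L) float counts

    def __post_init__(self) -> None:
        self.MAT = np.asarray(self.MAT, dtype=float)
        if self.MAT.shape[0] != N_ROWS:
            raise ValueError("MAT must have 16 rows")
        if (self.MAT < 0).any():
            raise ValueError("MAT counts must be non-negative")

    @property
    def x(self) -> np.ndarray:
        return self.MAT.sum(axis=1)

    @property
    def y(self) -> np.ndarray:
        return self.MAT.sum(axis=0)

    @property
    def N(self) -> float:
        return float(self.MAT.sum())


def accumulate_MAT(traces, L: int) -> FrequencyMatrix:
    """Count dinucleotide-by-column pairs over alignment traces.

    Each trace carries ``s1`` (window base codes, -1 marking a deletion in
    the sequence) and ``s2`` (1-based matrix column indices, -1 marking a
    deletion in the profile).  Position i contributes one count at
    ``(row(s1[i-1], s1[i]), s2[i])`` only when s1[i-1], s1[i] and s2[i] are
    all real; the first position and positions adjacent to a deletion are
    skipped.
    """
    mat = np.zeros((N_ROWS, L), dtype=float)
    for tr in traces:
        s1 = np.asarray(tr.s1, dtype=np.int64)
        s2 = np.asarray(tr.s2, dtype=np.int64)
        for i in range(1, len(s1)):
            if s1[i - 1] < 0 or s1[i] < 0 or s2[i] < 0:
                continue
            col = s2[i]
            if not 1 <= col <= L:
                raise ValueError(f"column index {col} outside [1, {L}]")
            mat[dinucleotide_row(s1[i - 1], s1[i]), col - 1] += 1
    return FrequencyMatrix(mat)


def standardize_M(freq: FrequencyMatrix) -> np.ndarray:
    """Standardised deviation of MAT from its independent-margin expectation.

    ``M(i,j) = (MAT(i,j) - N p(i,j)) / sqrt(N p(i,j) (1 - p(i,j)))`` with
    ``p(i,j) = x(i) y(j) / N^2``.  Cells with degenerate p (0 or 1) are set
    to 0 so that downstream normalisation stays bounded.
    """
    N = freq.N
    if N <= 0:
        raise ValueError("empty frequency matrix (no aligned positions)")
    p = np.outer(freq.x, freq.y) / (N * N)
    denom_sq = N * p * (1.0 - p)
    M = np.zeros_like(freq.MAT)
    ok = denom_sq > 0
    M[ok] = (freq.MAT[ok] - N * p[ok]) / np.sqrt(denom_sq[ok])
    return M


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_pwm(pwm: PWM, path, meta: dict | None = None) -> None:
    """Plain-text matrix with a JSON header line (L, p1, extra metadata)."""
    header = {"L": pwm.L, "p1": pwm.p1.tolist()}
    if meta:
        header.update(meta)
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        np.savetxt(fh, pwm.weights, fmt="%.10g")


def load_pwm(path) -> tuple[PWM, dict]:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("missing PWM header line")
        header = json.loads(first[1:])
        weights = np.loadtxt(fh)
    pwm = PWM(weights=weights.reshape(N_ROWS, -1),
              p1=np.asarray(header["p1"], dtype=float))
    return pwm, header
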