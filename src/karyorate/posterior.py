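"""Posterior summaries: credible intervals, the rate-difference statistic
(delta-R), mean-rate series, and Spearman rank correlations (including the
posterior-sample-wise variant across clades).

Quantiles everywhere use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .mcmc import Trace

__all__ = [
    "DeltaRResult",
    "SpearmanResult",
    "credible_interval",
    "delta_r",
    "mean_rate_series",
    "spearman",
    "posterior_spearman",
]


@dataclass
class DeltaRResult:
    """Per-posterior-sample difference of a rate between two trait states.

    ``verdict`` reads "a-higher" when the whole 95% interval lies above
    zero, "b-higher" when it lies below, "no-evidence" otherwise.
    """

    parameter: str
    samples: np.ndarray
    mean: float
    interval: tuple
    verdict: str


@dataclass
class SpearmanResult:
    rho: float
    S: float          # sum of squared rank differences
    p_value: float
    n: int
    undefined: bool = False


def credible_interval(samples, level: float = 0.95) -> tuple:
    """Central quantile interval at the given probability level."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    alpha = (1 - level) / 2
    lo, hi = np.quantile(samples, [alpha, 1 - alpha])
    return float(lo), float(hi)


def delta_r(trace: Trace, param_a: str, param_b: str,
            level: float = 0.95) -> DeltaRResult:
    """Rate difference ``param_a - param_b`` across posterior samples.

    The convention of the analyses this supports is a = the small-N_e
    (or sedentary) state's rate and b = the large-N_e (or migratory)
    state's rate, so an interval entirely below zero reads "the B state
    evolves faster".
    """
    diff = trace.column(param_a) - trace.column(param_b)
    lo, hi = credible_interval(diff, level)
    if lo > 0:
        verdict = "a-higher"
    elif hi < 0:
        verdict = "b-higher"
    else:
        verdict = "no-evidence"
    return DeltaRResult(f"{param_a}-{param_b}", diff, float(diff.mean()),
                        (lo, hi), verdict)


def mean_rate_series(trace: Trace, fission: str = "fission",
                     fusion: str = "fusion") -> np.ndarray:
    """Per-sample arithmetic mean of the fission and fusion rates."""
    return 0.5 * (trace.column(fission) + trace.column(fusion))


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(x, y, method: str = "t") -> SpearmanResult:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of the mid-ranks; S is the sum of
    squared rank differences.  ``method="t"`` gives the usual
    t-approximation p-value (two-sided); ``method="exact"`` enumerates all
    permutations (only sensible for n <= 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx, ry = _midranks(x), _midranks(y)
    S = float(np.sum((rx - ry) ** 2))
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return SpearmanResult(np.nan, S, np.nan, n, undefined=True)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "exact":
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho, S, p, n)


def posterior_spearman(samples_a: np.ndarray, samples_b: np.ndarray,
                       level: float = 0.95):
    """Sample-wise Spearman rho between two clade-by-sample rate matrices.

    For each posterior sample (column), the rank correlation across clades
    (rows) between the two series is computed.  Returns
    ``(rho_series, (lo, hi))``: one rho per posterior sample and its
    central credible interval.
    """
    A = np.asarray(samples_a, dtype=float)
    B = np.asarray(samples_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("matrices must share shape (clades, samples)")
    n_clades, n_samp = A.shape
    if n_clades < 3:
        raise ValueError("need at least 3 clades for a rank correlation")
    ra = np.apply_along_axis(_midranks, 0, A)
    rb = np.apply_along_axis(_midranks, 0, B)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    denom = np.sqrt((ra ** 2).sum(axis=0) * (rb ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra * rb).sum(axis=0) / denom
    return rho, credible_interval(rho[np.isfinite(rho)], level)
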