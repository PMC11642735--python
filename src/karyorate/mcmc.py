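"""Bayesian sampling of fission/fusion model parameters.

The sampler is univariate slice sampling with stepping-out (Neal 2003):
one full sweep over the parameters per recorded generation, initial
interval width 1.0, at most 20 step-outs apportioned randomly left/right.
Chains are initialised from independent uniform(0, 1) draws per parameter
and rates are constrained non-negative through the prior support.

Defaults mirror common practice for these models: 4000 generations with
the first 2000 discarded as burn-in for two-parameter fits, 10000
generations for six-parameter trait-linked fits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "uniform_prior",
    "exponential_prior",
    "parse_prior",
    "log_prior",
    "Trace",
    "mcmc_run",
    "discard_burnin",
    "thin",
]

DEFAULT_GENERATIONS = 4000
DEFAULT_GENERATIONS_LINKED = 10000
DEFAULT_BURNIN = 2000


@dataclass(frozen=True)
class PriorSpec:
    """Independent per-parameter priors.

    ``forms`` is a tuple of ``("uniform", lo, hi)`` or
    ``("exponential", rate)`` entries, one per parameter (a single entry is
    broadcast over all parameters at evaluation time).
    """

    forms: tuple

    def __post_init__(self):
        for f in self.forms:
            if f[0] == "uniform":
                _, lo, hi = f
                if not (0 <= lo < hi) or not np.isfinite(hi):
                    raise ValueError("uniform prior needs 0 <= lo < hi < inf")
            elif f[0] == "exponential":
                if f[1] <= 0:
                    raise ValueError("exponential prior rate must be > 0")
            else:
                raise ValueError(f"unknown prior form {f[0]!r}")

    def expanded(self, k: int) -> tuple:
        if len(self.forms) == k:
            return self.forms
        if len(self.forms) == 1:
            return self.forms * k
        raise ValueError(f"prior has {len(self.forms)} entries for "
                         f"{k} parameters")

    def log_density_one(self, form, x: float) -> float:
        if x < 0 or not np.isfinite(x):
            return -np.inf
        if form[0] == "uniform":
            _, lo, hi = form
            return -np.log(hi - lo) if lo <= x <= hi else -np.inf
        rate = form[1]
        return np.log(rate) - rate * x

    def log_density(self, params) -> float:
        params = np.atleast_1d(np.asarray(params, dtype=float))
        forms = self.expanded(len(params))
        return float(sum(self.log_density_one(f, x)
                         for f, x in zip(forms, params)))

    def to_json(self) -> str:
        return json.dumps([list(f) for f in self.forms])


def uniform_prior(lo: float = 0.0, hi: float = 100.0, k: int = 1) -> PriorSpec:
    return PriorSpec(tuple([("uniform", float(lo), float(hi))] * k))


def exponential_prior(rate: float = 0.1, k: int = 1) -> PriorSpec:
    return PriorSpec(tuple([("exponential", float(rate))] * k))


def parse_prior(text: str, k: int = 1) -> PriorSpec:
    """Parse ``"uniform:LO:HI"`` or ``"exp:RATE"`` into a PriorSpec."""
    parts = text.strip().lower().split(":")
    if parts[0] in ("uniform", "unif", "u"):
        lo, hi = (float(parts[1]), float(parts[2])) if len(parts) == 3 \
            else (0.0, 100.0)
        return uniform_prior(lo, hi, k)
    if parts[0] in ("exp", "exponential", "e"):
        rate = float(parts[1]) if len(parts) > 1 else 0.1
        return exponential_prior(rate, k)
    raise ValueError(f"cannot parse prior {text!r}")


def log_prior(params, spec: PriorSpec) -> float:
    """Joint log prior density of a parameter vector."""
    return spec.log_density(params)


@dataclass
class Trace:
    """A recorded MCMC chain: one row per generation."""

    names: tuple
    samples: np.ndarray          # (generations, k)
    log_prior: np.ndarray
    log_lik: np.ndarray
    generations: np.ndarray      # generation index (preserved over burn-in)
    seed: int
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        n, k = self.samples.shape
        if len(self.names) != k or len(self.log_prior) != n \
                or len(self.log_lik) != n or len(self.generations) != n:
            raise ValueError("inconsistent trace shapes")

    def __len__(self):
        return self.samples.shape[0]

    def column(self, name: str) -> np.ndarray:
        if name not in self.names:
            raise KeyError(f"no parameter {name!r} in trace "
                           f"(have {list(self.names)})")
        return self.samples[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"generation": self.generations,
                           "logprior": self.log_prior,
                           "loglik": self.log_lik})
        for j, nm in enumerate(self.names):
            df[nm] = self.samples[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, seed: int = -1, settings=None) -> "Trace":
        df = pd.read_csv(path)
        fixed = ["generation", "logprior", "loglik"]
        names = tuple(c for c in df.columns if c not in fixed)
        return cls(names, df[list(names)].to_numpy(float),
                   df["logprior"].to_numpy(float),
                   df["loglik"].to_numpy(float),
                   df["generation"].to_numpy(int), seed,
                   dict(settings or {}))


def _slice_update(logpost, x, j, lp_cur, rng, width, max_stepout):
    """One stepping-out slice-sampling update of coordinate j.

    Returns (new value, new log posterior, number of evaluations).
    """
    x0 = x[j]
    logy = lp_cur + np.log(rng.random())
    u = rng.random()
    left = x0 - width * u
    right = left + width
    evals = 0

    jmax = int(np.floor(max_stepout * rng.random()))
    kmax = max_stepout - 1 - jmax

    def f(val):
        nonlocal evals
        x[j] = val
        evals += 1
        return logpost(x)

    while jmax > 0 and f(left) > logy:
        left -= width
        jmax -= 1
    while kmax > 0 and f(right) > logy:
        right += width
        kmax -= 1

    while True:
        prop = left + rng.random() * (right - left)
        lp = f(prop)
        if lp > logy:
            x[j] = prop
            return prop, lp, evals
        if prop < x0:
            left = prop
        else:
            right = prop
        if right - left < 1e-300:
            x[j] = x0
            return x0, lp_cur, evals


def mcmc_run(model, prior: PriorSpec, n_generations: int = DEFAULT_GENERATIONS,
             seed: int = 0, param_names=None, width: float = 1.0,
             max_stepout: int = 20, init=None) -> Trace:
    """Sample the posterior of ``model`` (a log-likelihood callable).

    ``model(params) -> float`` receives the full parameter vector.  The
    number of parameters is taken from ``param_names`` (or
    ``model.param_names``).  Each generation is one full sweep of
    univariate slice updates.  The chain is reproducible given ``seed``.

    Initialisation draws every parameter from uniform(0, 1); if the
    posterior is not finite there, the draw is repeated (up to 100 times).
    """
    if n_generations < 1:
        raise ValueError("need at least one generation")
    if param_names is None:
        param_names = tuple(getattr(model, "param_names"))
    k = len(param_names)
    forms = prior.expanded(k)
    rng = np.random.default_rng(seed)

    def logpost(params):
        lp = prior.log_density(params)
        if not np.isfinite(lp):
            return -np.inf
        return lp + model(params)

    if init is not None:
        x = np.asarray(init, dtype=float).copy()
        lp_cur = logpost(x)
        if not np.isfinite(lp_cur):
            raise ValueError("supplied init has non-finite posterior")
    else:
        for attempt in range(100):
            x = rng.random(k)
            lp_cur = logpost(x)
            if np.isfinite(lp_cur):
                break
        else:
            raise RuntimeError("no finite posterior in 100 init draws")

    samples = np.empty((n_generations, k))
    lpri = np.empty(n_generations)
    llik = np.empty(n_generations)
    n_evals = 0
    for g in range(n_generations):
        for j in range(k):
            _, lp_cur, ev = _slice_update(logpost, x, j, lp_cur, rng,
                                          width, max_stepout)
            n_evals += ev
        samples[g] = x
        lpri[g] = prior.log_density(x)
        llik[g] = lp_cur - lpri[g]

    settings = {"sampler": "slice-stepping-out", "width": width,
                "max_stepout": max_stepout, "prior": prior.to_json(),
                "n_evaluations": n_evals}
    trace = Trace(tuple(param_names), samples, lpri, llik,
                  np.arange(n_generations), int(seed), settings)
    _log_diagnostics(trace)
    return trace


def _log_diagnostics(trace: Trace) -> None:
    """Emit effective sample size and Geweke z-scores to the log."""
    for j, nm in enumerate(trace.names):
        x = trace.samples[:, j]
        ess = _ess(x)
        z = _geweke(x)
        logger.info("param %-10s ESS=%.0f geweke_z=%.2f", nm, ess, z)


def _ess(x: np.ndarray) -> float:
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1))
    acf /= acf[0]
    s = 0.0
    for r in acf[1:]:
        if r < 0.05:
            break
        s += r
    return float(n / (1 + 2 * s))


def _geweke(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    n = len(x)
    a = x[: int(first * n)]
    b = x[int((1 - last) * n):]
    denom = np.sqrt(np.var(a) / len(a) + np.var(b) / len(b))
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def discard_burnin(trace: Trace, n_burn: int = DEFAULT_BURNIN) -> Trace:
    """Drop the first ``n_burn`` generations; records the discard."""
    if n_burn < 0:
        raise ValueError("burn-in must be non-negative")
    if n_burn >= len(trace):
        raise ValueError(f"burn-in {n_burn} >= chain length {len(trace)}")
    if n_burn == 0:
        return trace
    settings = dict(trace.settings)
    settings["burnin_discarded"] = settings.get("burnin_discarded", 0) + n_burn
    return Trace(trace.names, trace.samples[n_burn:].copy(),
                 trace.log_prior[n_burn:].copy(),
                 trace.log_lik[n_burn:].copy(),
                 trace.generations[n_burn:].copy(), trace.seed, settings)


def thin(trace: Trace, step: int) -> Trace:
    """Keep every ``step``-th generation (reduces autocorrelation)."""
    if step < 1:
        raise ValueError("thinning step must be >= 1")
    if step == 1:
        return trace
    settings = dict(trace.settings)
    settings["thinned_by"] = settings.get("thinned_by", 1) * step
    sl = slice(None, None, step)
    return Trace(trace.names, trace.samples[sl].copy(),
                 trace.log_prior[sl].copy(), trace.log_lik[sl].copy(),
                 trace.generations[sl].copy(), trace.seed, settings)
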