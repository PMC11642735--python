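"""Comparative statistics: the effective-population-size scoring index,
quartile binarization of abundance, tip-rate outlier detection, and
Blomberg's K phylogenetic-signal test.

The N_e index scores each clade (typically an order) on three proxies of
effective population size -- geographic range size, trophic level, and
body mass -- each contributing -1, 0 or +1, with positive totals read as
*small* population size.  Score directions:

* range size: lowest quartile -> +1 (small ranges, small populations),
  upper quartile -> -1;
* trophic level: carnivore -> +1, omnivore -> 0, herbivore -> -1;
* body mass: lowest quartile -> -1, upper quartile -> +1.

Totals of 1 or 2 classify a clade as small N_e, 0 as medium, -1 as large.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import dendropy

from . import ctmc
from .phylo_io import normalize_name, TROPHIC_LEVELS

__all__ = [
    "NeScoreTable",
    "TipRateRecord",
    "SignalResult",
    "quartile_thresholds",
    "score_species",
    "order_score",
    "ne_index",
    "score_orders",
    "binarize_by_quartiles",
    "tip_rates",
    "blomberg_k",
    "blomberg_k_test",
]

TROPHIC_SCORES = {"carnivore": 1, "omnivore": 0, "herbivore": -1}

NE_CLASSES = {-1: "large", 0: "medium", 1: "small", 2: "small"}


@dataclass
class TipRateRecord:
    species: str
    observed: int
    ancestral: int
    rate: int  # |observed - ancestral mode|


@dataclass
class SignalResult:
    K: float
    p_value: float
    n_permutations: int


def quartile_thresholds(values) -> tuple:
    """25th and 75th percentiles (linear-interpolation convention)."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for quartiles")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return float(q1), float(q3)


def score_species(trait: str, value, thresholds=None) -> int:
    """Score one species on one trait; returns -1, 0 or +1.

    ``thresholds`` is the (q1, q3) pair for numeric traits (mass, range);
    trophic values are the labels herbivore/omnivore/carnivore.
    Boundary convention: "lowest quartile" means value <= q1, "upper
    quartile" means value > q3.
    """
    if trait == "trophic":
        if value not in TROPHIC_SCORES:
            raise ValueError(f"unknown trophic level {value!r}; "
                             f"expected one of {TROPHIC_LEVELS}")
        return TROPHIC_SCORES[value]
    if thresholds is None:
        raise ValueError("numeric traits need (q1, q3) thresholds")
    q1, q3 = thresholds
    if trait == "mass":
        return -1 if value <= q1 else (1 if value > q3 else 0)
    if trait == "range":
        return 1 if value <= q1 else (-1 if value > q3 else 0)
    raise ValueError(f"unknown trait {trait!r}")


def order_score(scores) -> int:
    """Modal score of a clade's per-species scores; ties resolve to 0."""
    scores = list(scores)
    if not scores:
        raise ValueError("empty score list")
    counts = Counter(scores)
    top = counts.most_common()
    best = [s for s, c in top if c == top[0][1]]
    if len(best) > 1:
        warnings.warn(f"tied modal scores {sorted(best)}; assigning 0",
                      stacklevel=2)
        return 0
    return int(best[0])


def ne_index(scores) -> tuple:
    """Sum three per-trait clade scores into a population-size index.

    Returns ``(total, class)`` with class small/medium/large.  Totals
    outside the band observed in practice (-1..2) still map monotonically
    (more positive -> smaller populations) but are flagged with a warning.
    """
    scores = list(scores)
    if len(scores) != 3 or any(s not in (-1, 0, 1) for s in scores):
        raise ValueError("need exactly three scores from {-1, 0, +1}")
    total = int(sum(scores))
    if total in NE_CLASSES:
        return total, NE_CLASSES[total]
    warnings.warn(f"index total {total} outside the usual -1..2 band",
                  stacklevel=2)
    return total, ("small" if total > 0 else "large")


def score_orders(traits: pd.DataFrame, min_species: int = 1) -> pd.DataFrame:
    """Full scoring pipeline: species trait table -> per-order index table.

    ``traits`` must have columns order, mass_g, range_km2, trophic and be
    indexed by species.  Quartile thresholds for mass and range are taken
    over all species pooled; per-order scores are the modal per-species
    scores; the three scores sum to the index.  Returns a DataFrame with
    columns range_score, trophic_score, mass_score, total, ne_class.
    """
    needed = {"order", "mass_g", "range_km2", "trophic"}
    if not needed.issubset(traits.columns):
        raise ValueError(f"trait table needs columns {sorted(needed)}")
    mass_thr = quartile_thresholds(traits["mass_g"].dropna())
    range_thr = quartile_thresholds(traits["range_km2"].dropna())
    rows = {}
    for order, grp in traits.groupby("order"):
        if len(grp) < min_species:
            continue
        r = order_score([score_species("range", v, range_thr)
                         for v in grp["range_km2"].dropna()])
        t = order_score([score_species("trophic", v)
                         for v in grp["trophic"].dropna()])
        m = order_score([score_species("mass", v, mass_thr)
                         for v in grp["mass_g"].dropna()])
        total, klass = ne_index([r, t, m])
        rows[order] = {"range_score": r, "trophic_score": t, "mass_score": m,
                       "total": total, "ne_class": klass}
    return pd.DataFrame.from_dict(rows, orient="index")


#: alias documenting the tabular output of :func:`score_orders`
NeScoreTable = pd.DataFrame


def binarize_by_quartiles(abundance: dict) -> dict:
    """Split species into small/large population classes by abundance.

    Species at or below the first quartile are "small", species above the
    third quartile are "large"; the middle half is dropped from the
    output.  A degenerate distribution (q1 == q3) is an error.
    """
    names = [normalize_name(k) for k in abundance]
    vals = np.asarray(list(abundance.values()), dtype=float)
    q1, q3 = quartile_thresholds(vals)
    if q1 == q3:
        raise ValueError("degenerate abundance distribution: q1 == q3")
    out = {}
    for name, v in zip(names, vals):
        if v <= q1:
            out[name] = "small"
        elif v > q3:
            out[name] = "large"
    return out


def tip_rates(tree: dendropy.Tree, tip_states: dict,
              params: ctmc.ChromParams,
              space: ctmc.ChromStateSpace | None = None,
              pad: int = ctmc.DEFAULT_PAD,
              root_mode="weighted") -> list:
    """Tip-level rate proxies: |observed count - ancestral modal count|.

    The ancestral count for each tip is the mode of the marginal posterior
    distribution at the tip's immediate ancestor (ties broken toward the
    state nearest the tip's own count, then toward the lower count, so a
    tie never manufactures a spurious nonzero tip rate).  Species whose
    tip rate exceeds zero experienced recent count change relative to the
    reconstruction; filtering on ``rate > 0`` flags outlier lineages.
    """
    counts = {normalize_name(k): int(v) for k, v in tip_states.items()}
    if space is None:
        space = ctmc.build_state_space(counts.values(), pad)
    Q = ctmc.build_rate_matrix(params, space)
    marg = ctmc.marginal_ancestral_states(tree, counts, Q, root_mode)
    node_of = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    records = []
    states = space.states
    for name, obs in counts.items():
        parent = node_of[name].parent_node
        dist = marg[parent]
        best = dist.max()
        tied = states[np.isclose(dist, best, rtol=0, atol=1e-12)]
        anc = int(min(tied, key=lambda s: (abs(s - obs), s)))
        records.append(TipRateRecord(name, obs, anc, abs(obs - anc)))
    return records


def _bm_covariance(tree: dendropy.Tree):
    """Brownian-motion covariance: C[i, j] = depth of the tips' MRCA."""
    tips = list(tree.leaf_node_iter())
    labels = [t.taxon.label for t in tips]
    n = len(tips)
    C = np.zeros((n, n))
    depth = {}
    for node in tree.preorder_node_iter():
        d = 0.0 if node.parent_node is None else \
            depth[id(node.parent_node)] + node.edge.length
        depth[id(node)] = d
    tip_pos = {id(t): i for i, t in enumerate(tips)}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = [tip_pos[id(node)]]
            C[node._leafset[0], node._leafset[0]] = depth[id(node)]
            continue
        kids = node.child_nodes()
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]._leafset:
                    for j in kids[b]._leafset:
                        C[i, j] = C[j, i] = depth[id(node)]
        node._leafset = [i for kid in kids for i in kid._leafset]
    return labels, C


def blomberg_k(tree: dendropy.Tree, trait: dict) -> float:
    """Blomberg's K for a continuous trait on a tree.

    K compares the observed ratio of the trait's raw mean squared error
    (around the phylogenetic mean) to its phylogenetically corrected MSE
    against the ratio expected under Brownian motion; K ~ 1 indicates
    Brownian-like signal, K << 1 little signal.
    """
    labels, C = _bm_covariance(tree)
    vals = {normalize_name(k): float(v) for k, v in trait.items()}
    missing = [l for l in labels if l not in vals]
    if missing:
        raise ValueError(f"no trait value for {missing}")
    x = np.array([vals[l] for l in labels])
    return _k_statistic(C, x[:, None])[0]


def _k_statistic(C: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Vectorised K over trait columns of X given covariance C."""
    n = C.shape[0]
    if n < 4:
        raise ValueError("need at least 4 tips")
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular phylogenetic covariance matrix") from exc
    ones = np.ones((n, 1))
    Ci_ones = np.linalg.solve(C, ones)       # C^-1 1
    denom_a = float((ones.T @ Ci_ones).item())
    a_hat = (Ci_ones.T @ X) / denom_a        # phylogenetic mean per column
    R = X - a_hat                            # deviations
    mse0 = (R ** 2).sum(axis=0) / (n - 1)
    Z = np.linalg.solve(L, R)                # L^-1 R, so Z'Z = R' C^-1 R
    mse = (Z ** 2).sum(axis=0) / (n - 1)
    expected = (np.trace(C) - n / denom_a) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = (mse0 / mse) / expected
    return K


def blomberg_k_test(tree: dendropy.Tree, trait: dict, n_perm: int = 1000,
                    seed: int = 0) -> SignalResult:
    """Permutation test of phylogenetic signal via Blomberg's K.

    Tip values are shuffled across tips ``n_perm`` times; the one-sided
    upper-tail p-value uses the add-one correction
    ``p = (1 + #{K* >= K_obs}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    labels, C = _bm_covariance(tree)
    vals = {normalize_name(k): float(v) for k, v in trait.items()}
    missing = [l for l in labels if l not in vals]
    if missing:
        raise ValueError(f"no trait value for {missing}")
    x = np.array([vals[l] for l in labels])
    k_obs = float(_k_statistic(C, x[:, None])[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((len(x), n_perm))
    for i in range(n_perm):
        perms[:, i] = rng.permutation(x)
    k_perm = _k_statistic(C, perms)
    p = (1 + int(np.sum(k_perm >= k_obs))) / (n_perm + 1)
    return SignalResult(k_obs, float(p), n_perm)
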