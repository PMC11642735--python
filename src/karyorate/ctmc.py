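"""Continuous-time Markov chain machinery for chromosome-number evolution.

The model follows the classic fission/fusion parameterisation: a haploid
count ``n`` gains a chromosome (``n -> n+1``) at rate ``lam_fission`` and
loses one (``n -> n-1``) at rate ``lam_fusion``, both in events per lineage
per million years.  A trait-linked variant crosses the count space with a
binary trait: each trait state carries its own fission/fusion rates and the
trait itself flips at rates ``q01``/``q10``; a single instantaneous event
never changes count and trait simultaneously.

Likelihoods on trees use Felsenstein pruning.  Inside the likelihood the
action of ``exp(Q t)`` on a conditional-likelihood vector is computed by
uniformization (a Poisson-weighted power series in the stochastic matrix
``I + Q/mu``), which is fast, stable, and keeps every intermediate quantity
non-negative.  The dense matrix exponential (scaling-and-squaring Pade, via
scipy) remains the reference implementation exposed by
:func:`transition_probabilities`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.linalg import expm

import dendropy

from .phylo_io import normalize_name

__all__ = [
    "ChromStateSpace",
    "ChromParams",
    "LinkedChromParams",
    "RateMatrix",
    "LikelihoodResult",
    "build_state_space",
    "build_rate_matrix",
    "build_linked_rate_matrix",
    "transition_probabilities",
    "pruning_likelihood",
    "marginal_ancestral_states",
    "ChromLikelihood",
    "LinkedChromLikelihood",
]

DEFAULT_PAD = 5


@dataclass(frozen=True)
class ChromStateSpace:
    """Contiguous range of haploid chromosome counts ``n_min..n_max``."""

    n_min: int
    n_max: int

    def __post_init__(self):
        if self.n_min < 1 or self.n_max < self.n_min:
            raise ValueError("need 1 <= n_min <= n_max")

    @property
    def states(self) -> np.ndarray:
        return np.arange(self.n_min, self.n_max + 1)

    @property
    def size(self) -> int:
        return self.n_max - self.n_min + 1

    def index(self, count: int) -> int:
        if not (self.n_min <= count <= self.n_max):
            raise ValueError(f"count {count} outside state space "
                             f"[{self.n_min}, {self.n_max}]")
        return int(count) - self.n_min


@dataclass(frozen=True)
class ChromParams:
    """Fission/fusion rates (events per lineage per MY)."""

    lam_fission: float
    lam_fusion: float

    def __post_init__(self):
        for v in (self.lam_fission, self.lam_fusion):
            if not np.isfinite(v) or v < 0:
                raise ValueError("rates must be finite and non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.lam_fission, self.lam_fusion])


@dataclass(frozen=True)
class LinkedChromParams:
    """Trait-linked rates: per-trait fission/fusion plus trait flip rates."""

    lam_fission_0: float
    lam_fusion_0: float
    lam_fission_1: float
    lam_fusion_1: float
    q01: float
    q10: float

    def __post_init__(self):
        for v in self.as_array():
            if not np.isfinite(v) or v < 0:
                raise ValueError("rates must be finite and non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.lam_fission_0, self.lam_fusion_0,
                         self.lam_fission_1, self.lam_fusion_1,
                         self.q01, self.q10])


@dataclass(frozen=True)
class RateMatrix:
    """A generator matrix together with its state labeling.

    For linked models the flattened state index of ``(count n, trait b)``
    is ``b * space.size + (n - space.n_min)``; this convention is fixed
    because traces and ancestral-state tables reference it.
    """

    matrix: np.ndarray
    space: ChromStateSpace
    linked: bool = False

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    def state_index(self, count, trait=None) -> int:
        i = self.space.index(count)
        if not self.linked:
            return i
        if trait not in (0, 1):
            raise ValueError("linked model needs trait in {0, 1}")
        return trait * self.space.size + i

    def state_label(self, idx: int):
        if not self.linked:
            return int(self.space.n_min + idx)
        b, i = divmod(idx, self.space.size)
        return (int(self.space.n_min + i), int(b))


@dataclass
class LikelihoodResult:
    """Log-likelihood of tip data under a generator, plus bookkeeping."""

    log_likelihood: float
    root_mode: str
    root_conditional: np.ndarray | None = None
    node_conditionals: dict | None = None


def build_state_space(counts, pad: int = DEFAULT_PAD) -> ChromStateSpace:
    """State space covering observed counts with ``pad`` extra states on
    each side, floored at a haploid count of 1."""
    counts = [int(c) for c in counts]
    if not counts:
        raise ValueError("no counts supplied")
    if min(counts) < 1:
        raise ValueError("haploid counts must be >= 1")
    if pad < 0:
        raise ValueError("pad must be non-negative")
    return ChromStateSpace(max(1, min(counts) - pad), max(counts) + pad)


def build_rate_matrix(params: ChromParams, space: ChromStateSpace) -> RateMatrix:
    """Tridiagonal fission/fusion generator over the count space."""
    s = space.size
    Q = np.zeros((s, s))
    idx = np.arange(s - 1)
    Q[idx, idx + 1] = params.lam_fission
    Q[idx + 1, idx] = params.lam_fusion
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(Q, space, linked=False)


def build_linked_rate_matrix(params: LinkedChromParams,
                             space: ChromStateSpace) -> RateMatrix:
    """Generator on the crossed space {counts} x {trait 0, trait 1}."""
    s = space.size
    Q = np.zeros((2 * s, 2 * s))
    idx = np.arange(s - 1)
    Q[idx, idx + 1] = params.lam_fission_0
    Q[idx + 1, idx] = params.lam_fusion_0
    Q[s + idx, s + idx + 1] = params.lam_fission_1
    Q[s + idx + 1, s + idx] = params.lam_fusion_1
    all_idx = np.arange(s)
    Q[all_idx, s + all_idx] = params.q01
    Q[s + all_idx, all_idx] = params.q10
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(Q, space, linked=True)


def transition_probabilities(Q, t: float) -> np.ndarray:
    """``exp(Q t)`` with tiny negative round-off clipped to zero.

    Accepts a :class:`RateMatrix` or a bare generator array.
    """
    if t < 0:
        raise ValueError("elapsed time must be non-negative")
    M = Q.matrix if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    P = expm(M * t)
    if P.min() < -1e-12:
        raise FloatingPointError("matrix exponential produced negative entries")
    return np.clip(P, 0.0, None)


# --------------------------------------------------------------------------
# pruning likelihood
# --------------------------------------------------------------------------

@njit(cache=False)
def _prune_kernel(indptr, indices, data, mu, edge_child, edge_parent,
                  edge_len, partials):
    """Post-order pruning over a flattened tree.

    ``partials`` is (n_nodes, S), pre-filled with tip indicators and ones
    for internal nodes; it is modified in place.  ``data`` holds the CSR
    values of A = I + Q/mu.  Returns the accumulated log scaling factor
    (the root's unnormalised conditional likelihoods stay in ``partials``).
    """
    S = partials.shape[1]
    logscale = 0.0
    v = np.empty(S)
    term = np.empty(S)
    nxt = np.empty(S)
    for e in range(edge_child.shape[0]):
        child = edge_child[e]
        parent = edge_parent[e]
        mt = mu * edge_len[e]
        p = partials[child]
        if mt <= 0.0:
            for i in range(S):
                v[i] = p[i]
        else:
            # uniformization: v = sum_k Pois(k; mt) A^k p
            w = np.exp(-mt)
            cum = w
            for i in range(S):
                term[i] = p[i]
                v[i] = w * term[i]
            kmax = int(mt + 13.0 * np.sqrt(mt) + 45.0)
            k = 1
            wmax = w
            # stop only once the cumulative Poisson mass is exhausted AND
            # the weights have decayed to ~1e-18 of their peak, so entries
            # whose leading contribution is high-order (multi-step
            # transitions on short branches) keep full relative accuracy
            while (cum < 1.0 - 1e-14 or w > 1e-18 * wmax) and k <= kmax:
                for i in range(S):
                    acc = 0.0
                    for jj in range(indptr[i], indptr[i + 1]):
                        acc += data[jj] * term[indices[jj]]
                    nxt[i] = acc
                w *= mt / k
                cum += w
                if w > wmax:
                    wmax = w
                for i in range(S):
                    term[i] = nxt[i]
                    v[i] += w * term[i]
                k += 1
        tot = 0.0
        for i in range(S):
            tot += v[i]
        if not (tot > 0.0) or not np.isfinite(tot):
            return -np.inf
        logscale += np.log(tot)
        for i in range(S):
            partials[parent, i] *= v[i] / tot
    return logscale


class _TreeIndex:
    """Flattened post-order edge arrays for a dendropy tree."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        pos = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root = pos[id(tree.seed_node)]
        children, parents, lengths = [], [], []
        for n in nodes:
            if n.parent_node is not None:
                children.append(pos[id(n)])
                parents.append(pos[id(n.parent_node)])
                lengths.append(float(n.edge.length))
        self.edge_child = np.asarray(children, dtype=np.int64)
        self.edge_parent = np.asarray(parents, dtype=np.int64)
        self.edge_len = np.asarray(lengths, dtype=np.float64)
        self.tip_index = {n.taxon.label: pos[id(n)]
                         for n in nodes if n.is_leaf()}
        self.node_pos = pos
        self.nodes = nodes


def _tip_indicator(value, Q: RateMatrix) -> np.ndarray:
    """Map a tip observation to an indicator vector over the state set.

    Accepted forms: an int count (simple models); ``(count, trait)`` with
    trait 0/1 for linked models, where either element may be ``None`` to
    mark it as unobserved (indicator spread over all compatible states);
    or an explicit vector of length ``Q.size``.
    """
    S = Q.size
    vec = np.zeros(S)
    if isinstance(value, np.ndarray):
        if value.shape != (S,):
            raise ValueError("explicit tip vector has wrong length")
        return value.astype(float)
    if Q.linked:
        if not (isinstance(value, tuple) and len(value) == 2):
            raise ValueError("linked model tips need (count, trait) pairs")
        count, trait = value
        counts = [count] if count is not None else list(Q.space.states)
        traits = [trait] if trait is not None else [0, 1]
        for c in counts:
            for b in traits:
                vec[Q.state_index(c, b)] = 1.0
    else:
        if isinstance(value, tuple):
            value = value[0]
        vec[Q.space.index(value)] = 1.0
    return vec


def _root_weights(root_cond: np.ndarray, root_mode, Q: RateMatrix):
    """Root weighting applied to the root conditional likelihood vector."""
    if isinstance(root_mode, tuple) and root_mode[0] == "fixed":
        state = root_mode[1]
        idx = (Q.state_index(*state) if isinstance(state, tuple)
               else Q.state_index(state))
        w = np.zeros(Q.size)
        w[idx] = 1.0
        return w, "fixed"
    if root_mode == "flat":
        return np.full(Q.size, 1.0 / Q.size), "flat"
    if root_mode == "weighted":
        tot = root_cond.sum()
        if tot <= 0:
            return np.full(Q.size, 1.0 / Q.size), "weighted"
        return root_cond / tot, "weighted"
    raise ValueError(f"unknown root mode {root_mode!r}")


def _csr_pattern(M: np.ndarray):
    """CSR structure of the generator's sparsity pattern incl. diagonal."""
    mask = (M != 0.0)
    np.fill_diagonal(mask, True)
    rows, cols = np.nonzero(mask)
    indptr = np.zeros(M.shape[0] + 1, dtype=np.int64)
    np.cumsum(np.bincount(rows, minlength=M.shape[0]), out=indptr[1:])
    return rows, cols, indptr


def _prepare_partials(tree_index: _TreeIndex, tip_states, Q: RateMatrix):
    partials = np.ones((tree_index.n_nodes, Q.size))
    seen = set()
    for name, value in tip_states.items():
        name = normalize_name(name)
        if name not in tree_index.tip_index:
            continue
        try:
            vec = _tip_indicator(value, Q)
        except ValueError as exc:
            raise ValueError(f"tip state for {name!r}: {exc}") from exc
        partials[tree_index.tip_index[name]] = vec
        seen.add(name)
    missing = set(tree_index.tip_index) - seen
    if missing:
        raise ValueError(f"no tip state for species: {sorted(missing)}")
    return partials


def _loglik_from_partials(ti: _TreeIndex, partials: np.ndarray,
                          Q: RateMatrix, root_mode):
    M = Q.matrix
    mu = float(np.max(-np.diag(M))) if Q.size else 0.0
    if mu > 0:
        rows, cols, indptr = _csr_pattern(M)
        A = M / mu
        A[np.arange(Q.size), np.arange(Q.size)] += 1.0
        data = A[rows, cols]
    else:
        indptr = np.zeros(Q.size + 1, dtype=np.int64)
        cols = np.zeros(0, dtype=np.int64)
        data = np.zeros(0)
    logscale = _prune_kernel(indptr, cols.astype(np.int64), data, mu,
                             ti.edge_child, ti.edge_parent, ti.edge_len,
                             partials)
    if not np.isfinite(logscale):
        return -np.inf, partials[ti.root]
    root_cond = partials[ti.root]
    w, _ = _root_weights(root_cond, root_mode, Q)
    total = float(w @ root_cond)
    if total <= 0:
        return -np.inf, root_cond
    return float(np.log(total) + logscale), root_cond


def pruning_likelihood(tree: dendropy.Tree, tip_states, Q: RateMatrix,
                       root_mode="weighted") -> LikelihoodResult:
    """Felsenstein pruning log-likelihood of tip states under ``Q``.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree with branch lengths in MY; polytomies are fine.
    tip_states : mapping
        species name -> observation; see :func:`_tip_indicator` for forms.
    Q : RateMatrix
    root_mode : "weighted" | "flat" | ("fixed", state)
        "weighted" weights each root state by its share of the conditional
        likelihood (the common default of Bayesian character-model
        software); "flat" averages; ("fixed", n) or ("fixed", (n, b))
        conditions on a known root state.
    """
    ti = _TreeIndex(tree)
    partials = _prepare_partials(ti, tip_states, Q)
    ll, root_cond = _loglik_from_partials(ti, partials, Q, root_mode)
    mode_name = root_mode[0] if isinstance(root_mode, tuple) else root_mode
    return LikelihoodResult(ll, mode_name, root_conditional=root_cond.copy())


def marginal_ancestral_states(tree: dendropy.Tree, tip_states, Q: RateMatrix,
                              root_mode="weighted") -> dict:
    """Marginal posterior state distributions for every node.

    Returns a dict keyed by node: tip labels for leaves, the dendropy node
    object for internal nodes (the root included).  Distributions combine
    the standard down-pass conditional likelihoods with an up-pass of
    "outside" partial likelihoods; each sums to one.
    """
    ti = _TreeIndex(tree)
    S = Q.size
    down = _prepare_partials(ti, tip_states, Q)
    tip_vecs = down.copy()

    # per-edge transition matrices, cached by branch length
    P_cache: dict[float, np.ndarray] = {}

    def P_of(t):
        if t not in P_cache:
            P_cache[t] = transition_probabilities(Q, t)
        return P_cache[t]

    # down-pass (children before parents), with per-message normalisation
    messages = {}
    for e in range(len(ti.edge_child)):
        c, p, t = ti.edge_child[e], ti.edge_parent[e], ti.edge_len[e]
        v = P_of(t) @ down[c]
        tot = v.sum()
        if tot <= 0:
            raise FloatingPointError("zero conditional likelihood")
        v = v / tot
        messages[c] = v
        down[p] = down[p] * v

    root_cond = down[ti.root]
    w, _ = _root_weights(root_cond, root_mode, Q)

    # up-pass: outside[node] = prior/parent context excluding own subtree
    outside = {ti.root: w}
    order = list(range(len(ti.edge_child)))
    for e in reversed(order):  # parents before children in reverse postorder
        c, p, t = ti.edge_child[e], ti.edge_parent[e], ti.edge_len[e]
        ctx = outside[p] * down[p] / np.where(messages[c] > 0, messages[c], 1.0)
        ctx = np.where(messages[c] > 0, ctx, 0.0)
        up = P_of(t).T @ ctx
        outside[c] = up

    result = {}
    for n in ti.nodes:
        i = ti.node_pos[id(n)]
        base = tip_vecs[i] if n.is_leaf() else np.ones(S)
        post = outside[i] * (down[i] if not n.is_leaf() else base)
        tot = post.sum()
        if tot <= 0:
            raise FloatingPointError("degenerate marginal distribution")
        key = n.taxon.label if n.is_leaf() else n
        result[key] = post / tot
    return result


# --------------------------------------------------------------------------
# reusable likelihood closures for MCMC
# --------------------------------------------------------------------------

class ChromLikelihood:
    """Callable log-likelihood in (lam_fission, lam_fusion).

    Precomputes the tree traversal, tip indicators, and the generator's
    sparsity pattern once; each call rebuilds only the rate values.
    """

    param_names = ("fission", "fusion")

    def __init__(self, tree, tip_counts, space: ChromStateSpace | None = None,
                 pad: int = DEFAULT_PAD, root_mode="weighted"):
        counts = {normalize_name(k): v for k, v in tip_counts.items()}
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        missing = [l for l in labels if l not in counts]
        if missing:
            raise ValueError(f"no count for species: {missing}")
        if space is None:
            space = build_state_space([counts[l] for l in labels], pad)
        self.space = space
        self.root_mode = root_mode
        self.ti = _TreeIndex(tree)
        Q0 = build_rate_matrix(ChromParams(1.0, 1.0), space)
        self._template = _prepare_partials(self.ti, counts, Q0)
        self._rows, self._cols, self._indptr = _csr_pattern(Q0.matrix)
        self._S = space.size

    def rate_matrix(self, params) -> RateMatrix:
        lf, lu = float(params[0]), float(params[1])
        return build_rate_matrix(ChromParams(lf, lu), self.space)

    def __call__(self, params) -> float:
        lf, lu = float(params[0]), float(params[1])
        if lf < 0 or lu < 0 or not np.isfinite(lf + lu):
            return -np.inf
        Q = self.rate_matrix(params)
        partials = self._template.copy()
        mu = float(np.max(-np.diag(Q.matrix)))
        if mu <= 0:
            data = np.zeros(len(self._rows))
        else:
            A = Q.matrix / mu
            A[np.arange(self._S), np.arange(self._S)] += 1.0
            data = A[self._rows, self._cols]
        logscale = _prune_kernel(self._indptr, self._cols.astype(np.int64),
                                 data, mu, self.ti.edge_child,
                                 self.ti.edge_parent, self.ti.edge_len,
                                 partials)
        if not np.isfinite(logscale):
            return -np.inf
        root_cond = partials[self.ti.root]
        w, _ = _root_weights(root_cond, self.root_mode, Q)
        total = float(w @ root_cond)
        if total <= 0:
            return -np.inf
        return float(np.log(total) + logscale)


class LinkedChromLikelihood:
    """Callable log-likelihood in the six trait-linked parameters.

    Parameter order: fission0, fusion0, fission1, fusion1, q01, q10.
    ``tip_states`` maps species -> (count, trait); either element may be
    ``None`` (ambiguous; the tip indicator spreads over compatible states).
    """

    param_names = ("fission0", "fusion0", "fission1", "fusion1", "q01", "q10")

    def __init__(self, tree, tip_states, space: ChromStateSpace | None = None,
                 pad: int = DEFAULT_PAD, root_mode="weighted"):
        states = {normalize_name(k): v for k, v in tip_states.items()}
        if space is None:
            counts = [v[0] for v in states.values() if v[0] is not None]
            space = build_state_space(counts, pad)
        self.space = space
        self.root_mode = root_mode
        self.ti = _TreeIndex(tree)
        Q0 = build_linked_rate_matrix(
            LinkedChromParams(1, 1, 1, 1, 1, 1), space)
        self._template = _prepare_partials(self.ti, states, Q0)
        self._rows, self._cols, self._indptr = _csr_pattern(Q0.matrix)
        self._S = Q0.size

    def rate_matrix(self, params) -> RateMatrix:
        return build_linked_rate_matrix(
            LinkedChromParams(*[float(p) for p in params]), self.space)

    def __call__(self, params) -> float:
        params = np.asarray(params, dtype=float)
        if params.shape != (6,) or (params < 0).any() or \
                not np.isfinite(params).all():
            return -np.inf
        Q = self.rate_matrix(params)
        partials = self._template.copy()
        mu = float(np.max(-np.diag(Q.matrix)))
        if mu <= 0:
            data = np.zeros(len(self._rows))
        else:
            A = Q.matrix / mu
            A[np.arange(self._S), np.arange(self._S)] += 1.0
            data = A[self._rows, self._cols]
        logscale = _prune_kernel(self._indptr, self._cols.astype(np.int64),
                                 data, mu, self.ti.edge_child,
                                 self.ti.edge_parent, self.ti.edge_len,
                                 partials)
        if not np.isfinite(logscale):
            return -np.inf
        root_cond = partials[self.ti.root]
        w, _ = _root_weights(root_cond, self.root_mode, Q)
        total = float(w @ root_cond)
        if total <= 0:
            return -np.inf
        return float(np.log(total) + logscale)
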