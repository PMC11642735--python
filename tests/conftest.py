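import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import karyorate as kr


@pytest.fixture
def three_tip_tree():
    return kr.read_newick("((A:1.0,B:2.0):1.5,C:2.5);")


@pytest.fixture
def balanced_four_tip_tree():
    return kr.read_newick("((A:1.0,B:1.0):0.5,(C:0.8,D:1.2):0.7);")


def enumeration_loglik(tree, tip_states, Q, root_mode="weighted"):
    """Brute-force likelihood: sum over all interior-node state
    assignments of the product of branch transition probabilities.

    Independent of the package's pruning path: transition matrices come
    from scipy's expm and the sum is an explicit enumeration.
    """
    S = Q.size
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    P = {id(n): expm(Q.matrix * n.edge.length)
         for n in nodes if n.parent_node is not None}

    def tip_vec(name):
        v = tip_states[name]
        if isinstance(v, np.ndarray):
            return v
        if Q.linked:
            out = np.zeros(S)
            out[Q.state_index(*v)] = 1.0
            return out
        out = np.zeros(S)
        out[Q.space.index(v)] = 1.0
        return out

    L_root = np.zeros(S)
    for assign in itertools.product(range(S), repeat=len(internal)):
        amap = {id(n): s for n, s in zip(internal, assign)}
        p = 1.0
        for n in nodes:
            if n.parent_node is None:
                continue
            s_par = amap[id(n.parent_node)]
            if n.is_leaf():
                p *= float(P[id(n)][s_par] @ tip_vec(n.taxon.label))
            else:
                p *= P[id(n)][s_par, amap[id(n)]]
        L_root[amap[id(tree.seed_node)]] += p

    if isinstance(root_mode, tuple) and root_mode[0] == "fixed":
        state = root_mode[1]
        idx = (Q.state_index(*state) if isinstance(state, tuple)
               else Q.state_index(state))
        return float(np.log(L_root[idx]))
    if root_mode == "flat":
        return float(np.log(L_root.mean()))
    w = L_root / L_root.sum()
    return float(np.log(w @ L_root))


def enumeration_marginals(tree, tip_states, Q, root_mode="weighted"):
    """Brute-force per-node marginal state distributions."""
    S = Q.size
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    P = {id(n): expm(Q.matrix * n.edge.length)
         for n in nodes if n.parent_node is not None}
    post = {id(n): np.zeros(S) for n in internal}
    L_root = np.zeros(S)
    joint = []
    for assign in itertools.product(range(S), repeat=len(internal)):
        amap = {id(n): s for n, s in zip(internal, assign)}
        p = 1.0
        for n in nodes:
            if n.parent_node is None:
                continue
            s_par = amap[id(n.parent_node)]
            if n.is_leaf():
                p *= P[id(n)][s_par, Q.space.index(tip_states[n.taxon.label])]
            else:
                p *= P[id(n)][s_par, amap[id(n)]]
        joint.append((dict(amap), p))
        L_root[amap[id(tree.seed_node)]] += p
    if root_mode == "flat":
        w = np.full(S, 1.0 / S)
    else:
        w = L_root / L_root.sum()
    for amap, p in joint:
        pw = p * w[amap[id(tree.seed_node)]]
        for n in internal:
            post[id(n)][amap[id(n)]] += pw
    return {n: post[id(n)] / post[id(n)].sum() for n in internal}


def random_tree_and_states(rng, max_tips=5, max_states=6):
    """A random small tree plus random tip counts inside a small space."""
    n_tips = rng.integers(2, max_tips + 1)
    n_states = rng.integers(2, max_states + 1)
    n_min = int(rng.integers(1, 10))
    tree = kr.simulate_tree(int(n_tips), birth=1.0, death=0.0,
                            seed=int(rng.integers(2 ** 31)))
    space = kr.ChromStateSpace(n_min, n_min + n_states - 1)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    states = {lbl: int(rng.integers(n_min, n_min + n_states))
              for lbl in labels}
    return tree, space, states
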