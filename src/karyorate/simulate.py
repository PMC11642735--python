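"""Synthetic data with the statistical structure the analyses assume.

Every generator is deterministic under a fixed seed.  Trees come from a
birth-death process conditioned on the number of extant tips; chromosome
counts and linked binary traits evolve along branches by exact Gillespie
simulation of the same continuous-time Markov processes the likelihood
code fits, so simulation and inference share one model by construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import dendropy
from dendropy.simulate import treesim

from .ctmc import ChromParams, LinkedChromParams

__all__ = [
    "SimConfig",
    "simulate_tree",
    "simulate_chromosomes",
    "simulate_linked",
    "simulate_bm_trait",
    "make_order_trait_table",
]


@dataclass
class SimConfig:
    """A record of everything needed to regenerate one dataset."""

    n_tips: int
    birth: float
    death: float
    root_count: int
    params: object
    root_trait: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.birth <= self.death or self.death < 0:
            raise ValueError("need birth > death >= 0")
        if self.root_count < 1:
            raise ValueError("root count must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = list(np.atleast_1d(self.params.as_array()))
        return d


def simulate_tree(n_tips: int, birth: float, death: float = 0.0,
                  seed: int = 0) -> dendropy.Tree:
    """Ultrametric birth-death tree conditioned on ``n_tips`` extant tips.

    Branch lengths are in MY.  Tips are labeled ``T1..Tn``.  Simulation
    restarts on total extinction (up to 1000 attempts).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth <= death or death < 0:
        raise ValueError("need birth > death >= 0")
    rng = random.Random(int(seed))
    tree = None
    for _ in range(1000):
        try:
            tree = treesim.birth_death_tree(
                birth_rate=float(birth), death_rate=float(death),
                num_extant_tips=int(n_tips), rng=rng,
                repeat_until_success=False,
            )
            break
        except Exception:
            continue
    if tree is None:
        raise RuntimeError("total extinction in 1000 attempts")
    # the process stops exactly at the n-th birth, which leaves the youngest
    # cherry with zero-length edges; run time forward to the next event
    # (exponential waiting time) and stop just before it, so all branch
    # lengths are strictly positive and the process stays exact
    extra = rng.expovariate(n_tips * (birth + death))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += extra
    tree.seed_node.edge.length = None
    return tree


def _gillespie_branch(state: int, t: float, lam_fission: float,
                      lam_fusion: float, rng: np.random.Generator,
                      events=None, t0: float = 0.0) -> int:
    """Evolve a haploid count along one branch; fusion is disabled at 1."""
    remaining = t
    while True:
        up = lam_fission
        down = lam_fusion if state > 1 else 0.0
        total = up + down
        if total <= 0:
            return state
        wait = rng.exponential(1.0 / total)
        if wait > remaining:
            return state
        remaining -= wait
        if rng.random() < up / total:
            state += 1
            kind = "fission"
        else:
            state -= 1
            kind = "fusion"
        if events is not None:
            events.append((t0 + (t - remaining), kind, state))


def simulate_chromosomes(tree: dendropy.Tree, params: ChromParams,
                         root_count: int, seed: int = 0,
                         return_events: bool = False):
    """Evolve haploid counts down the tree under fission/fusion rates.

    Returns ``{species: count}`` (and the event log as a second element
    when ``return_events`` is set).
    """
    if root_count < 1:
        raise ValueError("root count must be >= 1")
    rng = np.random.default_rng(int(seed))
    events = [] if return_events else None
    state = {id(tree.seed_node): int(root_count)}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        state[id(node)] = _gillespie_branch(
            state[id(node.parent_node)], float(node.edge.length),
            params.lam_fission, params.lam_fusion, rng, events)
    tips = {lf.taxon.label: state[id(lf)] for lf in tree.leaf_node_iter()}
    return (tips, events) if return_events else tips


def _gillespie_linked(count: int, trait: int, t: float,
                      p: LinkedChromParams, rng: np.random.Generator):
    rates = ((p.lam_fission_0, p.lam_fusion_0, p.q01),
             (p.lam_fission_1, p.lam_fusion_1, p.q10))
    remaining = t
    while True:
        up, down, flip = rates[trait]
        if count <= 1:
            down = 0.0
        total = up + down + flip
        if total <= 0:
            return count, trait
        wait = rng.exponential(1.0 / total)
        if wait > remaining:
            return count, trait
        remaining -= wait
        u = rng.random() * total
        if u < up:
            count += 1
        elif u < up + down:
            count -= 1
        else:
            trait = 1 - trait


def simulate_linked(tree: dendropy.Tree, params: LinkedChromParams,
                    root_count: int, root_trait: int | None = 0,
                    seed: int = 0) -> dict:
    """Jointly evolve counts and a binary trait down the tree.

    ``root_trait=None`` draws the root trait from the flip-rate stationary
    distribution.  Returns ``{species: (count, trait)}``.
    """
    if root_count < 1:
        raise ValueError("root count must be >= 1")
    rng = np.random.default_rng(int(seed))
    if root_trait is None:
        tot = params.q01 + params.q10
        p1 = params.q01 / tot if tot > 0 else 0.5
        root_trait = int(rng.random() < p1)
    if root_trait not in (0, 1):
        raise ValueError("root trait must be 0, 1 or None")
    state = {id(tree.seed_node): (int(root_count), int(root_trait))}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        c, b = state[id(node.parent_node)]
        state[id(node)] = _gillespie_linked(c, b, float(node.edge.length),
                                            params, rng)
    return {lf.taxon.label: state[id(lf)] for lf in tree.leaf_node_iter()}


def simulate_bm_trait(tree: dendropy.Tree, sigma2: float, seed: int = 0,
                      root_value: float = 0.0) -> dict:
    """Brownian motion along branches: increments ~ N(0, sigma2 * t)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    rng = np.random.default_rng(int(seed))
    value = {id(tree.seed_node): float(root_value)}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = float(node.edge.length)
        value[id(node)] = value[id(node.parent_node)] + \
            rng.normal(0.0, np.sqrt(sigma2 * t))
    return {lf.taxon.label: value[id(lf)] for lf in tree.leaf_node_iter()}


# --------------------------------------------------------------------------
# order-structured trait tables for the N_e scoring pipeline
# --------------------------------------------------------------------------

# value bands, separated by wide gaps so pooled quartile thresholds always
# land between bands: band 0 (low) < band 1 (middle) < band 2 (high)
_BANDS = ((1.0, 10.0), (100.0, 200.0), (1000.0, 2000.0))

# which band realises a target score, per trait direction
_MASS_BAND = {-1: 0, 0: 1, 1: 2}     # low mass -> -1
_RANGE_BAND = {1: 0, 0: 1, -1: 2}    # low range -> +1
_TROPHIC_LABEL = {1: "carnivore", 0: "omnivore", -1: "herbivore"}


def _assign_bands(targets: list, m: int, band_of: dict) -> list:
    """Per-order band assignment giving each order a strict plurality of
    species in its target band while filling pooled band occupancies of
    exactly N/4 (low), N/2 (middle), N/4 (high), so that the pooled
    quartile thresholds fall in the gaps between bands."""
    k = len(targets)
    N = k * m
    if N % 4:
        raise ValueError("orders x species_per_order must be divisible by 4")
    cap = [N // 4, N // 2, N // 4]
    # start with every order fully in its target band, then move species
    # into underfull bands while preserving each order's strict plurality
    counts = [[0, 0, 0] for _ in range(k)]
    for o, t in enumerate(targets):
        counts[o][band_of[t]] = m
    occupancy = [sum(c[b] for c in counts) for b in range(3)]
    while any(occ > cp for occ, cp in zip(occupancy, cap)):
        b = max(range(3), key=lambda i: occupancy[i] - cap[i])
        under = [c for c in range(3) if occupancy[c] < cap[c]]
        moved = False
        for o in sorted(range(k), key=lambda o: -counts[o][b]):
            if band_of[targets[o]] != b or counts[o][b] == 0:
                continue
            for c in sorted(under, key=lambda c: counts[o][c]):
                # after the move the target band must still hold a strict
                # plurality over both other bands
                d = 3 - b - c
                if counts[o][b] - 1 > counts[o][c] + 1 and \
                        counts[o][b] - 1 > counts[o][d]:
                    counts[o][b] -= 1
                    counts[o][c] += 1
                    occupancy[b] -= 1
                    occupancy[c] += 1
                    moved = True
                    break
            if moved:
                break
        if not moved:
            raise ValueError(
                f"infeasible score targets: band occupancy {occupancy} "
                f"cannot be balanced to quartile capacities {cap}")
    return [[b for b in range(3) for _ in range(counts[o][b])]
            for o in range(k)]


def make_order_trait_table(n_orders: int, species_per_order: int,
                           score_targets: dict, seed: int = 0) -> pd.DataFrame:
    """Trait table whose quartile-and-mode pipeline recovers given scores.

    ``score_targets`` maps order name -> (range_score, trophic_score,
    mass_score), each in {-1, 0, +1}.  Numeric trait values are drawn
    inside well-separated bands sized so the pooled quartile thresholds
    fall in the gaps; trophic labels are deterministic.  An impossible
    target mix (too many orders claiming the same outer quartile) raises.

    The table also carries abundance (log-normal) and migratory columns so
    it is a complete input for every pipeline stage.
    """
    if n_orders < 4:
        raise ValueError("need at least 4 orders")
    if len(score_targets) != n_orders:
        raise ValueError("one score target triple per order required")
    orders = list(score_targets)
    targets = [tuple(score_targets[o]) for o in orders]
    for t in targets:
        if len(t) != 3 or any(s not in (-1, 0, 1) for s in t):
            raise ValueError(f"bad target triple {t}")
    m = species_per_order
    rng = np.random.default_rng(int(seed))

    range_bands = _assign_bands([t[0] for t in targets], m, _RANGE_BAND)
    mass_bands = _assign_bands([t[2] for t in targets], m, _MASS_BAND)

    rows = []
    for oi, order in enumerate(orders):
        trophic = _TROPHIC_LABEL[targets[oi][1]]
        for si in range(m):
            lo, hi = _BANDS[mass_bands[oi][si]]
            mass = rng.uniform(lo, hi)
            lo, hi = _BANDS[range_bands[oi][si]]
            rng_size = rng.uniform(lo, hi)
            rows.append({
                "species": f"{order} sp{si + 1}",
                "order": order,
                "mass_g": mass,
                "range_km2": rng_size,
                "trophic": trophic,
                "abundance": float(rng.lognormal(14, 2)),
                "migratory": int(rng.random() < 0.3),
            })
    return pd.DataFrame(rows).set_index("species")
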