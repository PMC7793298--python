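"""Trophic guilds as modules of the weighted bipartite diet network.

Consumers and prey groups form a two-mode network whose edge weights
are diet proportions. Modules are found by maximizing Barber's
weighted bipartite modularity

    Q = (1/m) * sum_ij (W_ij - r_i c_j / m) * [g_i == h_j]

with m the total edge weight, r and c the row/column strengths, via a
label-propagation optimizer with greedy module-merge and single-node
refinement (LPAwb+-style), restarted many times; the retained solution
is the ensemble medoid under the variation-of-information metric.
Consumer-side module membership defines the trophic guilds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import DietMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteNetwork",
    "ModulePartition",
    "bipartite_modularity",
    "maximize_modularity",
    "modularity_ensemble",
    "variation_of_information",
    "select_medoid",
    "cross_location_consistency",
    "guild_composition",
]


@dataclass
class BipartiteNetwork:
    """Weighted consumer x prey two-mode network."""

    weights: pd.DataFrame  # rows: consumers, cols: prey groups

    def __post_init__(self) -> None:
        W = self.weights.values
        if (W < 0).any():
            raise ValueError("negative edge weights")
        if (W.sum(axis=1) <= 0).any():
            raise ValueError("all-zero consumer rows are not allowed")

    @classmethod
    def from_diet(cls, diet: DietMatrix) -> "BipartiteNetwork":
        # drop prey groups never eaten: they carry no information
        mat = diet.matrix.loc[:, diet.matrix.sum(axis=0) > 0]
        return cls(weights=mat.copy())

    @property
    def consumers(self) -> list[str]:
        return list(self.weights.index)

    @property
    def prey(self) -> list[str]:
        return list(self.weights.columns)


@dataclass
class ModulePartition:
    """Joint module assignment of consumer and prey nodes."""

    consumers: dict[str, int]
    prey: dict[str, int]
    Q: float
    seed: int | None = None

    @property
    def n_modules(self) -> int:
        return len(set(self.consumers.values()) | set(self.prey.values()))

    def labels(self) -> dict[str, int]:
        """Joint labels over all nodes (prey names prefixed to avoid clashes)."""
        out = {f"C::{k}": v for k, v in self.consumers.items()}
        out.update({f"P::{k}": v for k, v in self.prey.items()})
        return out

    def canonical(self) -> "ModulePartition":
        """Relabel modules 0..M-1 by first appearance in node order."""
        remap: dict[int, int] = {}
        for lab in list(self.consumers.values()) + list(self.prey.values()):
            if lab not in remap:
                remap[lab] = len(remap)
        return ModulePartition(
            consumers={k: remap[v] for k, v in self.consumers.items()},
            prey={k: remap[v] for k, v in self.prey.items()},
            Q=self.Q, seed=self.seed,
        )


def _strengths(W: np.ndarray):
    m = W.sum()
    return m, W.sum(axis=1), W.sum(axis=0)


def _q_value(W: np.ndarray, g: np.ndarray, h: np.ndarray) -> float:
    """Barber modularity for consumer labels g and prey labels h."""
    labels = set(g.tolist()) | set(h.tolist())
    if len(labels) == 1:
        # the strength identity sum_ij (W_ij - r_i c_j / m) = 0 is exact
        return 0.0
    m, r, c = _strengths(W)
    B = W - np.outer(r, c) / m
    q = 0.0
    for lab in labels:
        ci = g == lab
        pj = h == lab
        if ci.any() and pj.any():
            q += B[np.ix_(ci, pj)].sum()
    return float(q / m)


def bipartite_modularity(net: BipartiteNetwork, part: ModulePartition) -> float:
    """Evaluate Barber's weighted bipartite modularity of a partition."""
    missing = [n for n in net.consumers if n not in part.consumers]
    missing += [n for n in net.prey if n not in part.prey]
    if missing:
        raise ValueError(f"node(s) missing from partition: {missing[:5]}")
    g = np.array([part.consumers[n] for n in net.consumers])
    h = np.array([part.prey[n] for n in net.prey])
    return _q_value(net.weights.values, g, h)


def _indicator(labels: np.ndarray, labs: np.ndarray) -> np.ndarray:
    """(n_labels, n_nodes) 0/1 membership matrix."""
    return (labels[None, :] == labs[:, None]).astype(float)


def _best_labels(scores: np.ndarray, labs: np.ndarray, own: np.ndarray,
                 other: np.ndarray, fresh_base: int) -> np.ndarray:
    """Per-node best label from a (n_labels, n_nodes) score matrix.

    Ties go to the smallest label id (labs is sorted). Nodes whose best
    score is not positive get a fresh singleton label (contribution 0),
    keeping their current label if already isolated.
    """
    best = scores.argmax(axis=0)
    best_score = scores[best, np.arange(scores.shape[1])]
    new = labs[best]
    nonpos = best_score <= 1e-15
    if nonpos.any():
        # a label is "isolated" for a node if no node on the other side
        # holds it and it is the node's own singleton
        other_set = set(other.tolist())
        own_counts = {}
        for lab in own.tolist():
            own_counts[lab] = own_counts.get(lab, 0) + 1
        for idx in np.flatnonzero(nonpos):
            cur = own[idx]
            if own_counts.get(cur, 0) == 1 and cur not in other_set:
                new[idx] = cur
            else:
                new[idx] = fresh_base + idx
    return new


def _propagate(W, g, h, B):
    """One synchronous label-propagation sweep (prey pass, consumer pass).

    Within each pass the opposite side's labels are fixed, so every
    node's best label follows from one matrix product; returns True if
    any label changed.
    """
    n_c, n_p = B.shape
    changed = False
    labs = np.array(sorted(set(g.tolist()) | set(h.tolist())))
    fresh = int(labs.max()) + 1
    # prey adopt the consumer-side module with the best contribution
    scores = _indicator(g, labs) @ B  # (L, n_p)
    new_h = _best_labels(scores, labs, h, g, fresh)
    if not np.array_equal(new_h, h):
        h[:] = new_h
        changed = True
    labs = np.array(sorted(set(g.tolist()) | set(h.tolist())))
    fresh = int(labs.max()) + 1 + n_p
    scores = _indicator(h, labs) @ B.T  # (L, n_c)
    new_g = _best_labels(scores, labs, g, h, fresh)
    if not np.array_equal(new_g, g):
        g[:] = new_g
        changed = True
    return changed


def _merge_refine(g, h, B):
    """Greedily merge module pairs while Q improves."""
    while True:
        labs = sorted(set(g.tolist()) | set(h.tolist()))
        if len(labs) < 2:
            return
        best_gain, best_pair = 0.0, None
        for a_idx in range(len(labs)):
            for b_idx in range(a_idx + 1, len(labs)):
                a, b = labs[a_idx], labs[b_idx]
                ca, pa = g == a, h == a
                cb, pb = g == b, h == b
                gain = B[np.ix_(ca, pb)].sum() + B[np.ix_(cb, pa)].sum()
                if gain > best_gain + 1e-12:
                    best_gain, best_pair = gain, (a, b)
        if best_pair is None:
            return
        a, b = best_pair
        g[g == b] = a
        h[h == b] = a


def _node_move_refine(W, g, h, B):
    """Hill-climb single-node moves until no move improves Q."""
    n_c, n_p = W.shape
    improved = True
    while improved:
        improved = False
        for i in range(n_c):
            labs = sorted(set(g.tolist()) | set(h.tolist()))
            cur = B[i, h == g[i]].sum()
            scores = [(B[i, h == lab].sum(), lab) for lab in labs if lab != g[i]]
            scores.append((0.0, max(labs) + 1))  # move to a fresh module
            sc, lab = max(scores, key=lambda t: t[0])
            if sc > cur + 1e-12:
                g[i] = lab
                improved = True
        for j in range(n_p):
            labs = sorted(set(g.tolist()) | set(h.tolist()))
            cur = B[g == h[j], j].sum()
            scores = [(B[g == lab, j].sum(), lab) for lab in labs if lab != h[j]]
            scores.append((0.0, max(labs) + 1))
            sc, lab = max(scores, key=lambda t: t[0])
            if sc > cur + 1e-12:
                h[j] = lab
                improved = True


def maximize_modularity(net: BipartiteNetwork, seed: int = 0,
                        restarts: int = 1, max_sweeps: int = 200) -> ModulePartition:
    """Maximize Barber modularity by seeded label propagation.

    Each restart initializes every consumer in its own module, runs
    label-propagation sweeps in a random node order, then greedy
    module merging and single-node hill-climbing. Deterministic given
    ``seed``; the best restart is returned.
    """
    W = net.weights.values.astype(float)
    n_c, n_p = W.shape
    m, r, c = _strengths(W)
    B = W - np.outer(r, c) / m
    rng = np.random.default_rng(seed)
    best_q, best_gh = -np.inf, None
    for restart in range(max(1, restarts)):
        if restart % 3 == 0:
            g = np.arange(n_c)  # every consumer its own module
            h = np.arange(n_c, n_c + n_p)  # fresh; first sweep assigns them
        elif restart % 3 == 1:  # coarse random start on the consumer side
            k0 = int(rng.integers(1, n_c + 1))
            g = rng.integers(0, k0, size=n_c)
            h = np.arange(n_c, n_c + n_p)
        else:  # random joint start explores merged configurations
            k0 = int(rng.integers(2, n_c + n_p + 1))
            g = rng.integers(0, k0, size=n_c)
            h = rng.integers(0, k0, size=n_p)
        seen: set[bytes] = set()
        for _ in range(max_sweeps):
            if not _propagate(W, g, h, B):
                break
            state = g.tobytes() + h.tobytes()
            if state in seen:  # synchronous updates can 2-cycle
                break
            seen.add(state)
        # alternate merge and single-node refinement to a fixpoint
        for _ in range(20):
            q_before = _q_value(W, g, h)
            _merge_refine(g, h, B)
            _node_move_refine(W, g, h, B)
            if _q_value(W, g, h) <= q_before + 1e-12:
                break
        q = _q_value(W, g, h)
        if q > best_q + 1e-15:
            best_q, best_gh = q, (g.copy(), h.copy())
    g, h = best_gh
    part = ModulePartition(
        consumers=dict(zip(net.consumers, g.tolist())),
        prey=dict(zip(net.prey, h.tolist())),
        Q=best_q, seed=seed,
    )
    return part.canonical()


def modularity_ensemble(net: BipartiteNetwork, n_runs: int = 500,
                        base_seed: int = 0, restarts: int = 1) -> list[ModulePartition]:
    """Run the optimizer ``n_runs`` times from distinct seeded starts."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_runs) % (2**31)
    return [maximize_modularity(net, seed=int(s), restarts=restarts) for s in seeds]


# ----------------------------------------------------------------------
# Variation of information
# ----------------------------------------------------------------------

def _vi_arrays(a: np.ndarray, b: np.ndarray) -> float:
    """VI between two integer label arrays over the same nodes."""
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    # identical up to relabeling -> exactly zero
    pairs = set(zip(ai.tolist(), bi.tolist()))
    if len(pairs) == len(set(ai.tolist())) == len(set(bi.tolist())):
        return 0.0
    k2 = bi.max() + 1
    joint = np.bincount(ai * k2 + bi, minlength=(ai.max() + 1) * k2) / n
    pa = np.bincount(ai) / n
    pb = np.bincount(bi) / n
    nz = joint > 0
    pj = joint.reshape(-1, k2)
    outer = np.outer(pa, pb).ravel()
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))
    h1 = -float(np.sum(pa * np.log(pa)))
    h2 = -float(np.sum(pb * np.log(pb)))
    del pj
    return max(h1 + h2 - 2.0 * mi, 0.0)


def _vi_from_labels(l1: dict, l2: dict) -> float:
    if set(l1) != set(l2):
        raise ValueError("partitions are over different node sets")
    nodes = sorted(l1)
    a = np.array([l1[v] for v in nodes])
    b = np.array([l2[v] for v in nodes])
    return _vi_arrays(a, b)


def variation_of_information(p1, p2) -> float:
    """VI = H(p1) + H(p2) - 2 I(p1; p2), natural log.

    Accepts two ModulePartition objects (compared over their joint node
    sets) or two plain label dicts over the same keys. Zero iff the
    partitions coincide up to relabeling.
    """
    if isinstance(p1, ModulePartition) and isinstance(p2, ModulePartition):
        return _vi_from_labels(p1.labels(), p2.labels())
    return _vi_from_labels(dict(p1), dict(p2))


def select_medoid(partitions: list[ModulePartition]) -> ModulePartition:
    """Partition minimizing total VI distance to all others (ties: first)."""
    if not partitions:
        raise ValueError("empty partition list")
    if len(partitions) == 1:
        return partitions[0]
    nodes = sorted(partitions[0].labels())
    arrays = []
    for p in partitions:
        lab = p.labels()
        if sorted(lab) != nodes:
            raise ValueError("partitions are over different node sets")
        arrays.append(np.array([lab[v] for v in nodes]))
    # group identical partitions (up to relabeling) to skip redundant VI
    def canon(a: np.ndarray) -> tuple:
        _, inv = np.unique(a, return_index=False, return_inverse=True)
        first = {}
        out = np.empty_like(inv)
        for i, v in enumerate(inv):
            if v not in first:
                first[v] = len(first)
            out[i] = first[v]
        return tuple(out.tolist())

    groups: dict[tuple, list[int]] = {}
    for idx, a in enumerate(arrays):
        groups.setdefault(canon(a), []).append(idx)
    reps = [idxs[0] for idxs in groups.values()]
    counts = np.array([len(idxs) for idxs in groups.values()], dtype=float)
    k = len(reps)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = _vi_arrays(arrays[reps[i]], arrays[reps[j]])
            dist[i, j] = dist[j, i] = d
    totals = dist @ counts  # total VI to all ensemble members
    best_group = int(np.argmin(totals))
    # ties broken by lowest run index among equal totals
    order = np.argsort(totals, kind="stable")
    tol = 1e-12
    candidates = [g for g in order if totals[g] <= totals[best_group] + tol]
    best_idx = min(min(groups[canon(arrays[reps[g]])]) for g in candidates)
    return partitions[best_idx]


def cross_location_consistency(partition: ModulePartition) -> float:
    """Fraction of multi-location species whose nodes share one module.

    Consumer nodes must be keyed ``species@location``. Returns NaN with
    a warning when no species occurs in more than one location.
    """
    by_species: dict[str, list[int]] = {}
    for node, mod in partition.consumers.items():
        if "@" not in node:
            raise ValueError(f"consumer node {node!r} is not keyed species@location")
        sp = node.split("@", 1)[0]
        by_species.setdefault(sp, []).append(mod)
    multi = {sp: mods for sp, mods in by_species.items() if len(mods) > 1}
    if not multi:
        logger.warning("no species found in more than one location")
        return float("nan")
    consistent = sum(1 for mods in multi.values() if len(set(mods)) == 1)
    return consistent / len(multi)


def guild_composition(partition: ModulePartition, net: BipartiteNetwork,
                      families: pd.Series | None = None) -> dict:
    """Module-level mean prey profiles and consumer-family tallies."""
    W = net.weights
    modules = sorted(set(partition.consumers.values()))
    profiles = {}
    fam_shares = {}
    for mod in modules:
        members = [c for c in net.consumers if partition.consumers[c] == mod]
        prof = W.loc[members].mean(axis=0)
        profiles[mod] = prof / prof.sum()
        if families is not None:
            sp = [m.split("@", 1)[0] for m in members]
            fam_shares[mod] = families.reindex(sp).value_counts(normalize=True)
    out = {"profiles": pd.DataFrame(profiles).T}
    if families is not None:
        out["family_shares"] = fam_shares
    return out
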