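"""Helix-level populations, detection calls, and coarse state clustering.

A helix's population in a variant is the summed weight of the structures
that contain every one of its pairs; uncertainties are propagated by
recomputing the sum per bootstrap replicate.  A helix is called *detected*
when its population exceeds its bootstrap error (signal-to-noise > 1).
Structures are coarse-grained into states by weighted k-medoids on the
base-pair symmetric-difference distance; the medioid (the member minimizing
population-weighted distance to its cluster) is each state's
representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bootstrap import BootstrapResult
from .structures import Helix, PairedStructure, bp_set_distance

__all__ = [
    "HelixCall",
    "StateCluster",
    "helix_universe",
    "helix_membership",
    "helix_populations",
    "cluster_states",
]


@dataclass(frozen=True)
class HelixCall:
    """A helix with its fitted population in one variant."""

    helix: Helix
    population: float
    sd: float
    variant: int  # row index in the fitted weight matrix

    @property
    def snr(self) -> float:
        if self.sd == 0.0:
            return float("inf") if self.population > 0 else 0.0
        return self.population / self.sd

    @property
    def detected(self) -> bool:
        return self.snr > 1.0


@dataclass
class StateCluster:
    """A coarse state: member structures, aggregate population, medioid."""

    members: list[int]          # structure indices
    population: float           # summed member weights
    medioid: int                # structure index of the representative

    def medioid_structure(self, structures: list[PairedStructure]) -> PairedStructure:
        return structures[self.medioid]


def helix_universe(structures: list[PairedStructure]) -> list[Helix]:
    """Distinct maximal helices across the ensemble, deduplicated by pair
    set.  Shifted registers are distinct helices."""
    seen: dict[tuple, Helix] = {}
    for s in structures:
        for h in s.helices:
            seen.setdefault(h.pairs, h)
    return [seen[k] for k in sorted(seen)]


def helix_membership(
    helices: list[Helix], structures: list[PairedStructure]
) -> np.ndarray:
    """Indicator matrix M[h, s] = 1 iff every pair of helix h is in s."""
    M = np.zeros((len(helices), len(structures)))
    for hi, h in enumerate(helices):
        hset = set(h.pairs)
        for si, s in enumerate(structures):
            if hset <= s.pairs:
                M[hi, si] = 1.0
    return M


def helix_populations(
    W: np.ndarray,
    structures: list[PairedStructure],
    bootstrap: BootstrapResult | None = None,
    helices: list[Helix] | None = None,
) -> list[list[HelixCall]]:
    """Per-variant helix populations with bootstrap uncertainties.

    Population of helix h in variant j is sum_s W[j,s] * [h contained in s].
    When a bootstrap result is given, the sd is the standard deviation of
    that sum recomputed in every replicate; otherwise sd = 0.
    """
    if helices is None:
        helices = helix_universe(structures)
    M = helix_membership(helices, structures)  # (H, r)
    pops = W @ M.T  # (m, H)
    if bootstrap is not None:
        rep_pops = np.einsum("bjs,hs->bjh", bootstrap.replicates, M)
        sds = rep_pops.std(axis=0)  # (m, H)
    else:
        sds = np.zeros_like(pops)
    calls: list[list[HelixCall]] = []
    for j in range(W.shape[0]):
        calls.append(
            [
                HelixCall(helix=h, population=float(pops[j, hi]),
                          sd=float(sds[j, hi]), variant=j)
                for hi, h in enumerate(helices)
            ]
        )
    return calls


def _weighted_medioid(
    members: list[int], D: np.ndarray, w: np.ndarray
) -> int:
    costs = [float((w[members] * D[k, members]).sum()) for k in members]
    return members[int(np.argmin(costs))]


def _kmedoids(
    D: np.ndarray, w: np.ndarray, k: int, max_iter: int = 100
) -> list[list[int]]:
    """Weighted k-medoids (PAM-style alternation) on a precomputed distance
    matrix; deterministic greedy farthest-point initialization seeded at the
    highest-weight structure."""
    r = len(w)
    medoids = [int(np.argmax(w))]
    while len(medoids) < k:
        dist_to_near = np.min(D[:, medoids], axis=1)
        score = w * dist_to_near
        score[medoids] = -1.0
        nxt = int(np.argmax(score))
        if score[nxt] <= 0:  # all remaining identical to a medoid
            break
        medoids.append(nxt)
    k = len(medoids)
    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new_medoids = []
        for ci in range(k):
            members = list(np.flatnonzero(assign == ci))
            if not members:
                members = [medoids[ci]]
            new_medoids.append(_weighted_medioid(members, D, w))
        if new_medoids == medoids:
            break
        medoids = new_medoids
    assign = np.argmin(D[:, medoids], axis=1)
    return [list(np.flatnonzero(assign == ci)) for ci in range(k)]


def _silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(D, labels, metric="precomputed"))


def cluster_states(
    structures: list[PairedStructure],
    wildtype_weights: np.ndarray,
    k: int | None = None,
) -> list[StateCluster]:
    """Cluster the ensemble into coarse states.

    Distance is the base-pair symmetric difference; clustering is weighted
    k-medoids using the wild-type weights.  When ``k`` is None it is chosen
    by silhouette score over 2..6 (capped at the number of distinct
    structures); identical ensembles collapse to a single state.
    """
    w = np.asarray(wildtype_weights, dtype=float)
    r = len(structures)
    if r == 0 or w.sum() <= 0:
        raise ValueError("need at least one structure with nonzero weight")
    D = np.zeros((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            D[i, j] = D[j, i] = bp_set_distance(structures[i], structures[j])

    n_distinct = len({s.pairs for s in structures})
    if k is not None and k > n_distinct:
        import warnings

        warnings.warn(f"k={k} exceeds {n_distinct} distinct structures; reduced")
        k = n_distinct
    if n_distinct == 1:
        clusters = [list(range(r))]
    elif k is not None:
        clusters = _kmedoids(D, w, k)
    else:
        best, best_score = None, -np.inf
        for kk in range(2, min(6, n_distinct) + 1):
            cl = _kmedoids(D, w, kk)
            if len(cl) < 2:
                continue
            labels = np.empty(r, dtype=int)
            for ci, members in enumerate(cl):
                labels[members] = ci
            try:
                score = _silhouette(D, labels)
            except ValueError:
                continue
            if score > best_score:
                best, best_score = cl, score
        clusters = best if best is not None else [list(range(r))]

    out = []
    for members in clusters:
        pop = float(w[members].sum())
        med = _weighted_medioid(members, D, w)
        out.append(StateCluster(members=members, population=pop, medioid=med))
    out.sort(key=lambda c: -c.population)
    return out
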