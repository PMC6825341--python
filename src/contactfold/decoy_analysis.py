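"""Decoy clustering, first-model selection, and convergence density.

Clustering follows the neighbour-count scheme: the decoy with the most
neighbours within an RMSD cutoff seeds the first cluster, its members are
removed, and the process repeats (up to five clusters). The cutoff adapts
within [3.5, 12] Å so the top cluster holds 10-70% of the decoys when
possible. The convergence density is Dc = (M / M_tot) / <R> with <R> the
mean RMSD of cluster members to the centroid.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .folding_engine import ChainConformation, DecoyEnsemble
from .geometry import superpose

MAX_CLUSTERS = 5
CUTOFF_MIN = 3.5
CUTOFF_MAX = 12.0
CUTOFF_STEP = 0.25
TOP_FRACTION_MIN = 0.10
TOP_FRACTION_MAX = 0.70
#: floor on <R> to keep Dc finite for degenerate single-point clusters
MEAN_RMSD_FLOOR = 0.5


@dataclass(frozen=True)
class ClusterSolution:
    members: tuple[int, ...]
    centroid_index: int
    mean_rmsd_to_centroid: float
    rmsd_cutoff: float

    def __post_init__(self):
        if self.centroid_index not in self.members:
            raise ValueError("centroid must be a cluster member")
        if self.mean_rmsd_to_centroid < 0:
            raise ValueError("mean RMSD must be non-negative")

    @property
    def M(self) -> int:
        return len(self.members)


def pairwise_rmsd(a: ChainConformation, b: ChainConformation) -> float:
    """Least RMSD over Cα after optimal rigid superposition."""
    if a.n_res != b.n_res:
        raise ValueError(
            f"conformation lengths differ: {a.n_res} vs {b.n_res}")
    rmsd, _, _, _ = superpose(a.ca, b.ca)
    return float(rmsd)


def rmsd_matrix(ens: DecoyEnsemble) -> np.ndarray:
    m = ens.M_tot
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = pairwise_rmsd(ens.decoys[i], ens.decoys[j])
    return D


def _cluster_at_cutoff(D: np.ndarray, cutoff: float,
                       max_clusters: int = MAX_CLUSTERS
                       ) -> list[ClusterSolution]:
    m = len(D)
    pool = list(range(m))
    solutions: list[ClusterSolution] = []
    while pool and len(solutions) < max_clusters:
        sub = D[np.ix_(pool, pool)]
        counts = (sub <= cutoff).sum(axis=1) - 1  # exclude self
        seed_local = int(np.argmax(counts))  # argmax takes the lowest index
        seed = pool[seed_local]
        members = tuple(pool[k] for k in range(len(pool))
                        if sub[seed_local, k] <= cutoff)
        mean_r = float(np.mean([D[seed, mem] for mem in members]))
        solutions.append(ClusterSolution(
            members=members, centroid_index=seed,
            mean_rmsd_to_centroid=mean_r, rmsd_cutoff=cutoff))
        member_set = set(members)
        pool = [k for k in pool if k not in member_set]
    return solutions


def _adapt_cutoff(D: np.ndarray) -> float:
    m = len(D)
    grid = np.arange(CUTOFF_MIN, CUTOFF_MAX + 1e-9, CUTOFF_STEP)
    fractions = []
    for c in grid:
        top = _cluster_at_cutoff(D, c, max_clusters=1)[0]
        frac = top.M / m
        if TOP_FRACTION_MIN <= frac <= TOP_FRACTION_MAX:
            return float(c)
        fractions.append(frac)
    # no cutoff lands in the band; pick the one closest to it
    fractions = np.array(fractions)
    dist = np.where(fractions < TOP_FRACTION_MIN,
                    TOP_FRACTION_MIN - fractions,
                    fractions - TOP_FRACTION_MAX)
    return float(grid[int(np.argmin(dist))])


def spicker_cluster(ens: DecoyEnsemble, cutoff: float | str = "auto",
                    max_clusters: int = MAX_CLUSTERS
                    ) -> list[ClusterSolution]:
    """Iterative neighbour-count clustering of a decoy ensemble.

    ``cutoff`` may be a fixed RMSD in Å or ``"auto"`` for the adaptive rule.
    """
    if ens.M_tot < 1:
        raise ValueError("ensemble is empty")
    D = rmsd_matrix(ens)
    if cutoff == "auto":
        cutoff = _adapt_cutoff(D)
    cutoff = float(cutoff)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return _cluster_at_cutoff(D, cutoff, max_clusters)


def convergence_density(sol: ClusterSolution, M_tot: int,
                        floor: float = MEAN_RMSD_FLOOR) -> float:
    """Dc = (M / M_tot) / <R>, with <R> floored to guard degenerate
    clusters."""
    if M_tot <= 0:
        raise ValueError("M_tot must be positive")
    mean_r = max(sol.mean_rmsd_to_centroid, floor)
    return (sol.M / M_tot) / mean_r


def select_first_model(solutions: Sequence[ClusterSolution],
                       ens: DecoyEnsemble) -> ChainConformation:
    """Centroid decoy of the largest cluster; ties keep the higher-ranked
    cluster."""
    if not solutions:
        raise ValueError("no cluster solutions")
    best = max(solutions, key=lambda s: s.M)  # max is stable on ties
    return ens.decoys[best.centroid_index]


def write_cluster_report(solutions: Sequence[ClusterSolution], M_tot: int,
                         path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\tM\tmean_rmsd\tDc\tcentroid_index\tcutoff\n")
        for rank, sol in enumerate(solutions, 1):
            dc = convergence_density(sol, M_tot)
            fh.write(f"{rank}\t{sol.M}\t{sol.mean_rmsd_to_centroid:.4f}\t"
                     f"{dc:.6f}\t{sol.centroid_index}\t"
                     f"{sol.rmsd_cutoff:.2f}\n")
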