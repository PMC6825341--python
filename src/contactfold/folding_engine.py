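"""Replica-exchange Monte Carlo assembly of coarse-grained chains.

Conformations are Cα traces with virtual Cβ atoms. The energy is the
contact-restraint well plus a minimal generic term set (harmonic Cα-Cα
bonds around 3.8 Å, soft-sphere excluded volume) and an optional
fragment-derived distance-profile term of the form -w * ln(p(d) + eps).
Moves are fragment substitution, pivot, and crankshaft; every accepted
conformation satisfies the bonded-geometry and excluded-volume invariants.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from . import geometry
from .contact_consensus import ConsensusContactSet
from .contact_potential import RestraintParams
from .geometry import (BOND_LENGTH, chain_is_valid, frame_transform,
                       rotate_about_axis, triad_frame, validate_chain,
                       virtual_cb)

__all__ = [
    "ChainConformation", "FragmentLibrary", "DistanceProfile",
    "SimulationConfig", "DecoyEnsemble", "EnergyModel",
    "build_distance_profile", "total_energy", "propose_move",
    "metropolis_accept", "replica_exchange_sweep", "run_folding",
    "extended_chain",
]


@dataclass
class ChainConformation:
    """Per-residue Cα coordinates plus virtual Cβ positions."""

    sequence: str
    ca: np.ndarray
    cb: np.ndarray | None = None

    def __post_init__(self):
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.shape != (len(self.sequence), 3):
            raise ValueError(
                f"coordinates {self.ca.shape} do not match sequence length "
                f"{len(self.sequence)}")
        if self.cb is None:
            self.cb = virtual_cb(self.ca)
        else:
            self.cb = np.asarray(self.cb, dtype=float)
            if self.cb.shape != self.ca.shape:
                raise ValueError("cb shape must match ca shape")

    @property
    def n_res(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        validate_chain(self.ca)

    def copy(self) -> "ChainConformation":
        return ChainConformation(self.sequence, self.ca.copy(),
                                 self.cb.copy())

    def with_ca(self, ca: np.ndarray) -> "ChainConformation":
        return ChainConformation(self.sequence, ca)


@dataclass
class FragmentLibrary:
    """Position-indexed Cα fragments of length 1-20."""

    fragments: dict[int, list[np.ndarray]]
    n_res: int
    top_n: int = 200

    def __post_init__(self):
        for start, frags in self.fragments.items():
            if len(frags) > self.top_n:
                raise ValueError(
                    f"position {start} holds {len(frags)} fragments "
                    f"(top_n={self.top_n})")
            for f in frags:
                if not (1 <= len(f) <= 20):
                    raise ValueError("fragment length must be in [1, 20]")

    def starts(self) -> list[int]:
        return sorted(self.fragments)

    def at(self, start: int) -> list[np.ndarray]:
        return self.fragments.get(start, [])

    def covering(self, i: int, j: int):
        """Yield (start, fragment) pairs covering residues i and j
        (0-based) within a single fragment."""
        lo, hi = min(i, j), max(i, j)
        for start, frags in self.fragments.items():
            if start > lo:
                continue
            for f in frags:
                if start + len(f) > hi:
                    yield start, f


@dataclass
class DistanceProfile:
    """Histogram of fragment-derived Cβ distances for one residue pair."""

    i: int
    j: int
    counts: np.ndarray
    bin_width: float = 0.5

    @property
    def n_obs(self) -> int:
        return int(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_obs == 0

    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    def energy(self, d: float, weight: float = 1.0,
               eps: float = 1e-3) -> float:
        """Knowledge-based term -w * ln(p(d) + eps); zero when empty."""
        if self.is_empty:
            return 0.0
        k = min(int(d / self.bin_width), len(self.counts) - 1)
        return -weight * float(np.log(self.probabilities()[k] + eps))


DEFAULT_WEIGHTS = {
    "contact": 2.0,
    "bond": 1.0,
    "clash": 5.0,
    "profile": 0.4,
}

DEFAULT_MOVE_PROBS = {
    "fragment": 0.5,
    "pivot": 0.3,
    "crankshaft": 0.2,
}


@dataclass
class SimulationConfig:
    """Replica-exchange Monte Carlo run parameters."""

    seed: int
    n_replicas: int = 8
    t_min: float = 0.5
    t_max: float = 5.0
    steps_per_replica: int = 3000
    swap_interval: int = 100
    snapshot_interval: int = 100
    n_snapshot_replicas: int = 2
    max_move_retries: int = 30
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    move_probs: dict = field(default_factory=lambda: dict(DEFAULT_MOVE_PROBS))

    def __post_init__(self):
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be positive")
        if self.t_min <= 0 or self.t_max < self.t_min:
            raise ValueError("temperature ladder must be positive increasing")
        if self.steps_per_replica < 0:
            raise ValueError("steps_per_replica must be non-negative")
        for name in ("swap_interval", "snapshot_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def temperature_ladder(self) -> np.ndarray:
        """Geometric ladder from t_min to t_max, strictly increasing."""
        if self.n_replicas == 1:
            return np.array([self.t_min])
        return np.geomspace(self.t_min, self.t_max, self.n_replicas)


@dataclass
class DecoyEnsemble:
    """Snapshots harvested from the low-temperature replicas."""

    decoys: list[ChainConformation]
    energies: list[float]

    def __post_init__(self):
        if not self.decoys:
            raise ValueError("a decoy ensemble must hold at least one decoy")
        if len(self.decoys) != len(self.energies):
            raise ValueError("decoys and energies must align")

    @property
    def M_tot(self) -> int:
        return len(self.decoys)


def build_distance_profile(frags: FragmentLibrary, i: int, j: int,
                           bin_width: float = 0.5,
                           max_distance: float = 40.0) -> DistanceProfile:
    """Histogram of Cβ distances between residues i and j (0-based) over
    every fragment that covers both positions.

    Pairs covered by no fragment yield an empty profile that contributes
    zero energy.
    """
    n_bins = int(np.ceil(max_distance / bin_width))
    counts = np.zeros(n_bins, dtype=int)
    for start, f in frags.covering(i, j):
        cb = virtual_cb(f)
        d = float(np.linalg.norm(cb[i - start] - cb[j - start]))
        counts[min(int(d / bin_width), n_bins - 1)] += 1
    return DistanceProfile(i=i, j=j, counts=counts, bin_width=bin_width)


class EnergyModel:
    """Precompiled energy terms for repeated evaluation during sampling."""

    PROFILE_EPS = 1e-3

    def __init__(self, n_res: int, cs: ConsensusContactSet | None,
                 params: RestraintParams | None = None,
                 profiles: Sequence[DistanceProfile] | None = None,
                 weights: dict | None = None):
        self.n_res = n_res
        self.weights = dict(DEFAULT_WEIGHTS)
        if weights:
            self.weights.update(weights)
        self.params = params or RestraintParams.from_length(max(n_res, 2))
        if cs is not None and len(cs) > 0:
            idx_j = max(c.j for c in cs.contacts)
            if idx_j > n_res:
                raise IndexError(
                    f"contact index {idx_j} exceeds chain length {n_res}")
            self._ci = np.array([c.i - 1 for c in cs.contacts])
            self._cj = np.array([c.j - 1 for c in cs.contacts])
            self._cu = np.array([c.u for c in cs.contacts])
        else:
            self._ci = np.empty(0, dtype=int)
            self._cj = np.empty(0, dtype=int)
            self._cu = np.empty(0)
        self._pi = np.empty(0, dtype=int)
        self._pj = np.empty(0, dtype=int)
        self._plogp = np.empty((0, 0))
        self._pbw = 0.5
        if profiles:
            used = [p for p in profiles if not p.is_empty]
            if used:
                widths = {p.bin_width for p in used}
                nbins = {len(p.counts) for p in used}
                if len(widths) > 1 or len(nbins) > 1:
                    raise ValueError("profiles must share binning")
                self._pbw = used[0].bin_width
                self._pi = np.array([p.i for p in used])
                self._pj = np.array([p.j for p in used])
                probs = np.stack([p.probabilities() for p in used])
                self._plogp = np.log(probs + self.PROFILE_EPS)

    # -- individual terms -------------------------------------------------

    def contact_term(self, conf: ChainConformation) -> float:
        if len(self._ci) == 0:
            return 0.0
        d = np.linalg.norm(conf.cb[self._ci] - conf.cb[self._cj], axis=1)
        u, d2 = self._cu, self.params.d2
        rising = -(u / 2.0) * (1.0 - np.sin(
            (d - (8.0 + d2) / 2.0) / (d2 - 8.0) * np.pi))
        upper = (u / 2.0) * (1.0 + np.sin(
            (d - (80.0 + d2) / 2.0) / (80.0 - d2) * np.pi))
        e = np.select([d <= 8.0, d <= d2, d < 80.0, d >= 80.0],
                      [-u, rising, upper, u])
        return float(e.sum())

    def bond_term(self, conf: ChainConformation) -> float:
        b = np.linalg.norm(np.diff(conf.ca, axis=0), axis=1)
        return float(((b - BOND_LENGTH) ** 2).sum())

    def clash_term(self, conf: ChainConformation,
                   soft_radius: float = 3.8) -> float:
        """Soft-sphere repulsion for non-bonded Cα pairs below 3.8 Å."""
        n = conf.n_res
        if n < 3:
            return 0.0
        d = pdist(conf.ca)[geometry.nonbonded_condensed_mask(n)]
        viol = soft_radius - d
        viol = viol[viol > 0]
        return float((viol ** 2).sum()) if len(viol) else 0.0

    def profile_term(self, conf: ChainConformation) -> float:
        if len(self._pi) == 0:
            return 0.0
        d = np.linalg.norm(conf.cb[self._pi] - conf.cb[self._pj], axis=1)
        bins = np.minimum((d / self._pbw).astype(int),
                          self._plogp.shape[1] - 1)
        return float(-self._plogp[np.arange(len(bins)), bins].sum())

    # -- totals -----------------------------------------------------------

    def terms(self, conf: ChainConformation) -> dict[str, float]:
        w = self.weights
        return {
            "contact": w["contact"] * self.contact_term(conf),
            "bond": w["bond"] * self.bond_term(conf),
            "clash": w["clash"] * self.clash_term(conf),
            "profile": w["profile"] * self.profile_term(conf),
        }

    def total(self, conf: ChainConformation) -> float:
        return float(sum(self.terms(conf).values()))


def total_energy(conf: ChainConformation, cs: ConsensusContactSet | None,
                 profiles: Sequence[DistanceProfile] | None = None,
                 config: SimulationConfig | None = None,
                 params: RestraintParams | None = None) -> float:
    """Weighted sum of restraint, bond, excluded-volume, and optional
    profile terms."""
    weights = config.weights if config is not None else None
    model = EnergyModel(conf.n_res, cs, params=params, profiles=profiles,
                        weights=weights)
    return model.total(conf)


# -- moves ----------------------------------------------------------------


def _fragment_substitution(ca: np.ndarray, frags: FragmentLibrary,
                           rng: np.random.Generator) -> np.ndarray | None:
    starts = [s for s in frags.starts()
              if any(3 <= len(f) <= len(ca) - s for f in frags.at(s))]
    if not starts:
        return None
    p = starts[int(rng.integers(len(starts)))]
    options = [f for f in frags.at(p) if 3 <= len(f) <= len(ca) - p]
    f = options[int(rng.integers(len(options)))]
    l = len(f)
    seg_old = ca[p:p + l]
    # place the fragment so its first atom and initial orientation match
    # the current segment start; internal geometry comes from the fragment
    R, t = frame_transform(triad_frame(f[0], f[1], f[2]),
                           triad_frame(seg_old[0], seg_old[1], seg_old[2]))
    seg_new = f @ R.T + t
    new = ca.copy()
    new[p:p + l] = seg_new
    if p + l < len(ca):
        # rigidly re-attach everything downstream of the segment
        Rd, td = frame_transform(
            triad_frame(seg_old[-3], seg_old[-2], seg_old[-1]),
            triad_frame(seg_new[-3], seg_new[-2], seg_new[-1]))
        new[p + l:] = ca[p + l:] @ Rd.T + td
    return new


def _pivot(ca: np.ndarray, rng: np.random.Generator) -> np.ndarray | None:
    n = len(ca)
    if n < 3:
        return None
    k = int(rng.integers(1, n - 1))
    axis = rng.normal(size=3)
    angle = rng.normal(0.0, 0.35)
    new = ca.copy()
    new[k + 1:] = rotate_about_axis(ca[k + 1:], ca[k], axis, angle)
    return new


def _crankshaft(ca: np.ndarray, rng: np.random.Generator) -> np.ndarray | None:
    n = len(ca)
    if n < 4:
        return None
    k = int(rng.integers(0, n - 3))
    m = int(rng.integers(k + 2, min(k + 9, n)))
    axis = ca[m] - ca[k]
    if np.linalg.norm(axis) < 1e-9:
        return None
    angle = rng.normal(0.0, 0.6)
    new = ca.copy()
    new[k + 1:m] = rotate_about_axis(ca[k + 1:m], ca[k], axis, angle)
    return new


_MOVES = {
    "fragment": _fragment_substitution,
    "pivot": _pivot,
    "crankshaft": _crankshaft,
}


def propose_move(conf: ChainConformation, frags: FragmentLibrary | None,
                 rng: np.random.Generator,
                 move_probs: dict | None = None,
                 max_retries: int = 30) -> ChainConformation:
    """Draw one geometry-preserving move; fall back to the identity move
    when every retry violates chain invariants."""
    probs = dict(move_probs or DEFAULT_MOVE_PROBS)
    if frags is None or not frags.fragments:
        probs.pop("fragment", None)
    names = sorted(probs)
    weights = np.array([probs[m] for m in names], dtype=float)
    cumulative = np.cumsum(weights / weights.sum())
    for _ in range(max_retries):
        move = names[int(np.searchsorted(cumulative, rng.random()))]
        if move == "fragment":
            new_ca = _fragment_substitution(conf.ca, frags, rng)
        else:
            new_ca = _MOVES[move](conf.ca, rng)
        if new_ca is None:
            continue
        if chain_is_valid(new_ca):
            return conf.with_ca(new_ca)
    return conf


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Standard Metropolis criterion: accept with min(1, exp(-dE/T))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    if not np.isfinite(delta_e):
        return False
    return bool(rng.random() < np.exp(-delta_e / temperature))


def replica_exchange_sweep(replicas: list, rng: np.random.Generator,
                           parity: int = 0) -> list:
    """Propose swaps between adjacent replicas (alternating even/odd
    pairing) with acceptance min(1, exp((1/T_a - 1/T_b)(E_a - E_b))).

    ``replicas`` is a list of ``[conf, energy, temperature]`` entries,
    ordered by temperature; conformations and energies are exchanged in
    place, temperatures stay with the slot.
    """
    temps = [r[2] for r in replicas]
    if any(b <= a for a, b in zip(temps, temps[1:])):
        raise ValueError("temperature ladder must be strictly increasing")
    for a in range(parity % 2, len(replicas) - 1, 2):
        b = a + 1
        conf_a, e_a, t_a = replicas[a]
        conf_b, e_b, t_b = replicas[b]
        log_p = (1.0 / t_a - 1.0 / t_b) * (e_a - e_b)
        if log_p >= 0 or rng.random() < np.exp(log_p):
            replicas[a] = [conf_b, e_b, t_a]
            replicas[b] = [conf_a, e_a, t_b]
    return replicas


def extended_chain(sequence: str) -> ChainConformation:
    """Deterministic near-extended starting conformation with ideal bonds."""
    n = len(sequence)
    i = np.arange(n)
    # gentle zigzag keeps i, i+2 pairs clear of the excluded-volume floor
    ca = np.stack([3.7 * i, 0.8 * (i % 2), np.zeros(n)], axis=1)
    validate_chain(ca)
    return ChainConformation(sequence, ca)


def run_folding(sequence: str, cs: ConsensusContactSet | None,
                frags: FragmentLibrary | None,
                config: SimulationConfig,
                profiles: Sequence[DistanceProfile] | None = None,
                log_path=None) -> DecoyEnsemble:
    """Replica-exchange Monte Carlo assembly.

    Snapshots are harvested from the ``n_snapshot_replicas`` coldest
    replicas at the end of every exchange sweep. Runs are bit-reproducible
    for a fixed config (including seed).
    """
    model = EnergyModel(len(sequence), cs, profiles=profiles,
                        weights=config.weights)
    ladder = config.temperature_ladder
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicas + 1)
    rngs = [np.random.default_rng(s) for s in seeds[:-1]]
    swap_rng = np.random.default_rng(seeds[-1])

    start = extended_chain(sequence)
    replicas = [[start.copy(), model.total(start), float(t)] for t in ladder]

    decoys: list[ChainConformation] = [start.copy()]
    energies: list[float] = [replicas[0][1]]

    log_rows = []
    if config.steps_per_replica > 0:
        n_sweeps = max(1, config.steps_per_replica // config.swap_interval)
        for sweep in range(n_sweeps):
            for r, rng in enumerate(rngs):
                conf, e_curr, t = replicas[r]
                for _ in range(config.swap_interval):
                    cand = propose_move(conf, frags, rng,
                                        config.move_probs,
                                        config.max_move_retries)
                    if cand is conf:
                        continue
                    e_new = model.total(cand)
                    if metropolis_accept(e_new - e_curr, t, rng):
                        conf, e_curr = cand, e_new
                replicas[r] = [conf, e_curr, t]
            replica_exchange_sweep(replicas, swap_rng, parity=sweep % 2)
            for r in range(min(config.n_snapshot_replicas,
                               config.n_replicas)):
                decoys.append(replicas[r][0].copy())
                energies.append(replicas[r][1])
            if log_path is not None:
                for r, (conf, e, t) in enumerate(replicas):
                    log_rows.append((sweep, r, t, e))
    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write("sweep\treplica\ttemperature\tenergy\n")
            for sweep, r, t, e in log_rows:
                fh.write(f"{sweep}\t{r}\t{t:.4f}\t{e:.6f}\n")
    return DecoyEnsemble(decoys=decoys, energies=energies)
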