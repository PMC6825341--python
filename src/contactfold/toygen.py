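"""Synthetic fixtures: toy folds, contact lists, fragment libraries, MSAs.

Everything here is seeded and bit-reproducible. Toy structures are ideal
secondary-structure elements joined by arc loops; contact lists are the
true map corrupted to a requested precision; MSAs are built from identity
clusters so a requested effective sequence count can be dialed in.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .contact_consensus import (Category, ConsensusContactSet, Contact,
                                PredictorOutput, separation_class, top_count)
from .folding_engine import ChainConformation, FragmentLibrary
from .geometry import (BOND_MAX, BOND_MIN, GeometryError, chain_is_valid,
                       validate_chain)
from .msa_stats import AlignedSequenceSet, effective_count

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

Topology = Literal["helix_bundle", "beta_hairpin", "mixed"]

MIN_RESIDUES = 20
MAX_RESIDUES = 120

#: minimum sequence separation for a pair to count as a true contact
TRUE_CONTACT_MIN_SEPARATION = 6

#: stand-in precision tiers for the four predictor accuracy categories
DEFAULT_TIER_PRECISION: dict[str, float] = {
    "very_high": 0.80,
    "high": 0.65,
    "medium": 0.50,
    "low": 0.35,
}


@dataclass(frozen=True)
class ToySpec:
    topology: Topology
    n_res: int
    seed: int

    def __post_init__(self):
        if not (MIN_RESIDUES <= self.n_res <= MAX_RESIDUES):
            raise ValueError(
                f"n_res must be in [{MIN_RESIDUES}, {MAX_RESIDUES}]")
        if self.topology not in ("helix_bundle", "beta_hairpin", "mixed"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass(frozen=True)
class CorruptionSpec:
    precision: float
    list_length_rule: Category
    ranking_noise: float
    seed: int

    def __post_init__(self):
        if not (0 < self.precision <= 1):
            raise ValueError("precision must be in (0, 1]")
        if self.ranking_noise < 0:
            raise ValueError("ranking_noise must be non-negative")


# -- ideal secondary structure -------------------------------------------

_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
# twist giving an exact 3.8 Å Calpha-Calpha bond on the ideal helix
_HELIX_TWIST = 2.0 * math.asin(
    math.sqrt(3.8 ** 2 - _HELIX_RISE ** 2) / (2.0 * _HELIX_RADIUS))

_STRAND_STEP = 3.3
_STRAND_PLEAT = math.sqrt(3.8 ** 2 - _STRAND_STEP ** 2) / 2.0


def _helix(n: int, center_xy, z0: float, direction: int,
           phase: float = 0.0) -> np.ndarray:
    k = np.arange(n)
    ang = phase + direction * _HELIX_TWIST * k
    return np.stack([
        center_xy[0] + _HELIX_RADIUS * np.cos(ang),
        center_xy[1] + _HELIX_RADIUS * np.sin(ang),
        z0 + direction * _HELIX_RISE * k,
    ], axis=1)


def _bezier(a, c, b, t):
    t = t[:, None]
    return (1 - t) ** 2 * a + 2 * (1 - t) * t * c + t ** 2 * b


def _perpendicularize(direction: np.ndarray, ab: np.ndarray):
    """Project a bulge direction onto the plane perpendicular to the chord;
    a symmetric arc needs this. Returns None when degenerate."""
    d = direction - np.dot(direction, ab) * ab
    norm = np.linalg.norm(d)
    return d / norm if norm > 1e-8 else None


def _arc_interior(a, b, direction, k, target, ts):
    """Interior points of a quadratic arc from a to b, bulge bisected so the
    mean chord hits the ideal bond length; None when infeasible."""

    def interior(h: float) -> np.ndarray:
        pts = _bezier(a, (a + b) / 2 + h * direction, b, ts)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        idx = [np.searchsorted(cum, cum[-1] * (m + 1) / (k + 1))
               for m in range(k)]
        return pts[np.clip(idx, 0, len(pts) - 1)]

    def mean_chord(h: float) -> float:
        chain = np.vstack([a, interior(h), b])
        return float(np.linalg.norm(np.diff(chain, axis=0), axis=1).mean())

    lo, hi = 0.0, 1.0
    while mean_chord(hi) < target and hi < 64:
        hi *= 2
    if mean_chord(hi) < target:
        return None
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if mean_chord(mid) < target:
            lo = mid
        else:
            hi = mid
    pts = interior(0.5 * (lo + hi))
    chords = np.linalg.norm(
        np.diff(np.vstack([a, pts, b]), axis=0), axis=1)
    if chords.min() < BOND_MIN or chords.max() > BOND_MAX:
        return None
    return pts


def _connect(a: np.ndarray, b: np.ndarray, bulge_dir: np.ndarray,
             target: float = 3.8,
             context_before: np.ndarray | None = None,
             context_after: np.ndarray | None = None,
             avoid: np.ndarray | None = None) -> np.ndarray:
    """Interior loop points from ``a`` to ``b`` on an outward-bulging arc.

    Every chord lands in the bonded window; when junction context and an
    avoid-set are given, the loop is also required to clear the excluded
    volume locally and against the rest of the structure. Several bulge
    directions are tried before giving up.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = float(np.linalg.norm(b - a))
    ab = (b - a) / max(d, 1e-9)
    ts = np.linspace(0.0, 1.0, 512)

    axes = [np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]),
            np.array([0.0, 0.0, 1.0])]
    raw_candidates = [bulge_dir]
    for e in axes:
        raw_candidates += [bulge_dir + 0.7 * e, bulge_dir - 0.7 * e]
    raw_candidates += axes + [-e for e in axes]
    candidates = []
    for c in raw_candidates:
        p = _perpendicularize(np.asarray(c, float), ab)
        if p is not None:
            candidates.append(p)

    def acceptable(interior: np.ndarray) -> bool:
        before = (np.asarray(context_before, float)
                  if context_before is not None and len(context_before)
                  else a[None, :])
        after = (np.asarray(context_after, float)
                 if context_after is not None and len(context_after)
                 else b[None, :])
        local = np.vstack([before, interior, after])
        if not chain_is_valid(local):
            return False
        if avoid is not None and len(avoid) and len(interior):
            gaps = np.linalg.norm(
                interior[:, None, :] - np.asarray(avoid, float)[None, :, :],
                axis=2)
            if gaps.min() < 3.5:
                return False
        return True

    for k in range(0, 12):
        if k == 0:
            if BOND_MIN <= d <= BOND_MAX and acceptable(np.empty((0, 3))):
                return np.empty((0, 3))
            continue
        if d / (k + 1) > BOND_MAX:
            continue  # even a straight bridge over-stretches the bonds
        for direction in candidates:
            interior = _arc_interior(a, b, direction, k, target, ts)
            if interior is not None and acceptable(interior):
                return interior
    raise GeometryError(
        f"could not bridge {d:.2f} Å with a feasible loop")


def _assemble(segments: Sequence[np.ndarray],
              bulge_dirs: Sequence[np.ndarray]):
    """Concatenate structured segments, inserting arc loops between them.

    Returns the coordinates and the realised size of every loop.
    """
    parts = [segments[0]]
    loop_sizes = []
    for seg, bulge in zip(segments[1:], bulge_dirs):
        placed = np.vstack(parts)
        loop = _connect(placed[-1], seg[0], bulge,
                        context_before=placed[-4:],
                        context_after=seg[:4],
                        avoid=np.vstack([placed[:-2], seg[2:]]))
        loop_sizes.append(len(loop))
        if len(loop):
            parts.append(loop)
        parts.append(seg)
    return np.vstack(parts), loop_sizes


def _split_lengths(n: int, n_segments: int, loop_budget: int) -> list[int]:
    usable = max(n_segments, n - loop_budget)
    base = usable // n_segments
    lengths = [base] * n_segments
    for k in range(usable - base * n_segments):
        lengths[k] += 1
    return lengths


def _build_adaptive(n: int, n_segments: int, make_segments,
                    loop_guess: int = 2) -> np.ndarray:
    """Assemble segments + loops, re-splitting segment lengths until the
    realised loop sizes add up to exactly ``n`` residues."""
    budget = loop_guess * (n_segments - 1)
    adjust = 0
    for _ in range(10):
        lengths = _split_lengths(n, n_segments, budget)
        # absorb the residue-count mismatch in the final segment: loops
        # upstream of it are unaffected by its length
        lengths[-1] = max(3, lengths[-1] + adjust)
        segments, bulges = make_segments(lengths)
        ca, loop_sizes = _assemble(segments, bulges)
        if len(ca) == n:
            return ca
        adjust += n - len(ca)
    raise GeometryError(
        f"could not assemble a {n}-residue chain (got {len(ca)})")


def _out(c_from, c_to) -> np.ndarray:
    """Horizontal direction from one axis centre toward another; used to
    bulge loops away from the bundle interior."""
    v = np.array([c_to[0] - c_from[0], c_to[1] - c_from[1], 0.0])
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _helix_bundle_ca(n: int) -> np.ndarray:
    d = 9.8
    centers = [(0.0, 0.0), (d, 0.0), (d / 2, d * math.sqrt(3) / 2)]
    up = np.array([0.0, 0.0, 1.0])

    def make(lengths):
        z1_top = _HELIX_RISE * (lengths[0] - 1)
        segs = [
            _helix(lengths[0], centers[0], 0.0, +1),
            _helix(lengths[1], centers[1], z1_top, -1, phase=math.pi),
            _helix(lengths[2], centers[2], 0.0, +1, phase=math.pi / 2),
        ]
        bulges = [up + 0.6 * _out(centers[2], centers[0]),
                  -up + 0.6 * _out(centers[0], centers[1])]
        return segs, bulges

    return _build_adaptive(n, 3, make)


def _strand(n: int, x0: float, direction: int, z: float,
            y_phase: int = 0) -> np.ndarray:
    k = np.arange(n)
    return np.stack([
        x0 + direction * _STRAND_STEP * k,
        _STRAND_PLEAT * np.where((k + y_phase) % 2 == 0, 1.0, -1.0),
        np.full(n, z),
    ], axis=1)


def _beta_hairpin_ca(n: int) -> np.ndarray:
    def make(lengths):
        s1 = _strand(lengths[0], 0.0, +1, 0.0)
        s2 = _strand(lengths[1], s1[-1, 0], -1, 5.0, y_phase=1)
        return [s1, s2], [np.array([1.0, 0.0, 0.5])]

    return _build_adaptive(n, 2, make, loop_guess=1)


def _vertical_strand(n: int, x0: float, z0: float, direction: int,
                     y_phase: int = 0) -> np.ndarray:
    k = np.arange(n)
    return np.stack([
        np.full(n, x0),
        _STRAND_PLEAT * np.where((k + y_phase) % 2 == 0, 1.0, -1.0),
        z0 + direction * _STRAND_STEP * k,
    ], axis=1)


def _mixed_ca(n: int) -> np.ndarray:
    def make(lengths):
        helix = _helix(lengths[0], (0.0, 0.0), 0.0, +1)
        z_top = helix[-1, 2]
        s1 = _vertical_strand(lengths[1], 8.5, z_top, -1)
        s2 = _vertical_strand(lengths[2], 13.5, s1[-1, 2], +1, y_phase=1)
        bulges = [np.array([1.0, 0.0, 1.0]), np.array([0.5, 0.0, -1.0])]
        return [helix, s1, s2], bulges

    return _build_adaptive(n, 3, make)


_BUILDERS = {
    "helix_bundle": _helix_bundle_ca,
    "beta_hairpin": _beta_hairpin_ca,
    "mixed": _mixed_ca,
}


def random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def make_toy_structure(spec: ToySpec) -> ChainConformation:
    """Idealised fold with seeded coordinate jitter; deterministic per
    seed and guaranteed to satisfy chain-geometry invariants."""
    rng = np.random.default_rng(spec.seed)
    ca = _BUILDERS[spec.topology](spec.n_res)
    if len(ca) != spec.n_res:
        raise GeometryError(
            f"builder produced {len(ca)} residues, wanted {spec.n_res}")
    validate_chain(ca)
    sequence = random_sequence(spec.n_res, rng)
    jitter = 0.05
    for _ in range(6):
        trial = ca + rng.normal(0.0, jitter, size=ca.shape)
        if chain_is_valid(trial):
            return ChainConformation(sequence, trial)
        jitter *= 0.5
    return ChainConformation(sequence, ca)


def true_contacts(conf: ChainConformation, threshold: float = 8.0,
                  min_separation: int = TRUE_CONTACT_MIN_SEPARATION
                  ) -> ConsensusContactSet:
    """All residue pairs with Cβ distance <= threshold and sequence
    separation >= ``min_separation``, at unit weight."""
    n = conf.n_res
    contacts = []
    for i in range(n):
        for j in range(i + min_separation, n):
            d = float(np.linalg.norm(conf.cb[i] - conf.cb[j]))
            if d <= threshold:
                contacts.append(Contact(
                    i=i + 1, j=j + 1, u=1.0,
                    separation_class=separation_class(i + 1, j + 1)))
    return ConsensusContactSet(tuple(contacts), n)


def corrupt_contacts(truth: ConsensusContactSet, spec: CorruptionSpec,
                     L: int) -> PredictorOutput:
    """Ranked contact list with a controlled fraction of true pairs.

    The list length follows the tier's top-count rule. True pairs come from
    the head of the truth ranking; false pairs are drawn uniformly from
    non-contacts at the same separation floor. When the truth is too small
    to fill the true quota the list shrinks so the realised precision stays
    within one pair of the request.
    """
    rng = np.random.default_rng(spec.seed)
    n_list = top_count(spec.list_length_rule, L)
    n_true = int(round(spec.precision * n_list))
    if n_true > len(truth):
        n_true = len(truth)
        n_list = max(1, int(math.floor(n_true / spec.precision)))
        n_true = int(round(spec.precision * n_list))
    n_false = n_list - n_true
    truth_pairs = [(c.i, c.j) for c in truth.contacts]
    true_sel = truth_pairs[:n_true]
    truth_set = set(truth_pairs)
    non_contacts = [
        (i, j)
        for i in range(1, L + 1)
        for j in range(i + TRUE_CONTACT_MIN_SEPARATION, L + 1)
        if (i, j) not in truth_set
    ]
    if n_false > len(non_contacts):
        raise ValueError(
            f"cannot sample {n_false} false pairs from "
            f"{len(non_contacts)} non-contacts")
    false_idx = rng.choice(len(non_contacts), size=n_false, replace=False)
    false_sel = [non_contacts[k] for k in false_idx]
    pairs = true_sel + false_sel
    order = rng.permutation(len(pairs))
    confidences = np.sort(
        np.clip(np.linspace(0.95, 0.40, len(pairs))
                + rng.normal(0.0, spec.ranking_noise, size=len(pairs)),
                0.01, 1.0))[::-1]
    ranked = tuple(
        (pairs[k][0], pairs[k][1], float(conf))
        for k, conf in zip(order, confidences))
    return PredictorOutput(
        predictor_name=f"toy_{spec.list_length_rule}_p{spec.precision:.2f}",
        category=spec.list_length_rule, pairs=ranked)


def synth_msa(L: int, n: int, target_nf: float, seed: int,
              tolerance: float = 0.10) -> AlignedSequenceSet:
    """Ungapped MSA whose effective count lands within ``tolerance`` of
    ``target_nf``.

    Sequences are organised into identity clusters (within-cluster identity
    above the 0.8 threshold, between-cluster identity well below), so the
    effective count is approximately the cluster count divided by sqrt(L);
    the cluster count is searched until the target is met.
    """
    if target_nf > n / math.sqrt(L) + 1e-9:
        raise ValueError("target_nf exceeds the n/sqrt(L) ceiling")
    if target_nf < 1.0 / math.sqrt(L) - 1e-9:
        raise ValueError("target_nf below the 1/sqrt(L) floor")
    rng = np.random.default_rng(seed)
    k_ideal = target_nf * math.sqrt(L)
    candidates = sorted({
        int(np.clip(round(k_ideal) + delta, 1, n)) for delta in (0, -1, 1)
    }, key=lambda k: abs(k - k_ideal))

    aa = np.array(list(AMINO_ACIDS))
    ancestor = rng.integers(0, len(aa), size=L)

    def mutate(base: np.ndarray, rate: float) -> np.ndarray:
        mask = rng.random(L) < rate
        out = base.copy()
        out[mask] = rng.integers(0, len(aa), size=mask.sum())
        return out

    last_err = None
    for k in candidates:
        cluster_roots = [mutate(ancestor, 0.7) for _ in range(k)]
        sizes = [n // k + (1 if c < n % k else 0) for c in range(k)]
        rows = []
        idx = 0
        for root, size in zip(cluster_roots, sizes):
            for _ in range(size):
                member = mutate(root, 0.02)
                name = "query" if idx == 0 else f"seq{idx}"
                rows.append((name, "".join(aa[member])))
                idx += 1
        msa = AlignedSequenceSet("query", tuple(rows))
        nf = effective_count(msa).nf
        err = abs(nf - target_nf) / target_nf
        if err <= tolerance:
            return msa
        last_err = err
    raise ValueError(
        f"target Nf {target_nf} unreachable for L={L}, n={n} "
        f"(best relative error {last_err:.3f})")


def make_fragment_library(conf: ChainConformation,
                          lengths: Sequence[int] = tuple(range(3, 10)),
                          per_position: int = 200,
                          jitter: float = 0.1,
                          seed: int = 0) -> FragmentLibrary:
    """Native-derived fragments with seeded coordinate jitter."""
    if per_position < 1:
        raise ValueError("per_position must be positive")
    for l in lengths:
        if not (1 <= l <= 20):
            raise ValueError("fragment lengths must be in [1, 20]")
    rng = np.random.default_rng(seed)
    n = conf.n_res
    fragments: dict[int, list[np.ndarray]] = {}
    for start in range(n):
        valid_lengths = [l for l in lengths if start + l <= n]
        if not valid_lengths:
            continue
        frags = []
        for _ in range(per_position):
            l = valid_lengths[int(rng.integers(len(valid_lengths)))]
            native = conf.ca[start:start + l]
            frag = native.copy()
            for _ in range(6 if jitter > 0 else 0):
                cand = _repair_bonds(
                    native + rng.normal(0.0, jitter, size=native.shape))
                if chain_is_valid(cand):
                    frag = cand
                    break
            frags.append(frag)
        fragments[start] = frags
    return FragmentLibrary(fragments=fragments, n_res=n,
                           top_n=max(per_position, 200))


def _repair_bonds(ca: np.ndarray, target: float = 3.8) -> np.ndarray:
    """Rescale each bond of a jittered fragment back into the bonded window
    while keeping the perturbed directions."""
    if len(ca) < 2:
        return ca
    out = np.empty_like(ca)
    out[0] = ca[0]
    for k in range(1, len(ca)):
        step = ca[k] - ca[k - 1]
        norm = np.linalg.norm(step)
        if norm < 1e-9:
            step = np.array([target, 0.0, 0.0])
            norm = target
        length = float(np.clip(norm, BOND_MIN + 0.05, BOND_MAX - 0.05))
        out[k] = out[k - 1] + step * (length / norm)
    return out


def random_walk_chain(n: int, seed: int,
                      max_attempts: int = 200) -> ChainConformation:
    """Self-avoiding random walk baseline with ideal bond lengths."""
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        pts = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            placed = False
            for _ in range(100):
                step = rng.normal(size=3)
                step *= 3.8 / np.linalg.norm(step)
                cand = pts[-1] + step
                if len(pts) < 2 or np.min(np.linalg.norm(
                        np.array(pts[:-1]) - cand, axis=1)) >= 3.5:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            ca = np.array(pts)
            if chain_is_valid(ca):
                return ChainConformation(random_sequence(n, rng), ca)
    raise GeometryError(f"failed to grow a {n}-residue random walk")
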