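"""Model confidence scoring and TM-score machinery.

The confidence score combines alignment depth, contact satisfaction, and
simulation convergence:

    C-score = 0.2 * ln(Nf) + ln(Sr * Dc)

with Sr the weighted satisfaction rate of the top-L long-range contacts
(Sr = (1/n_L) sum_i delta_i w_i^2) and Dc the cluster convergence density.
The estimated model quality follows the linear calibration

    TM-score = 0.0659 * C-score + 0.477

whose residual root-mean-square deviation is 0.084.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .contact_consensus import ConsensusContactSet, long_range_subset
from .folding_engine import ChainConformation
from .geometry import superpose

TM_SLOPE = 0.0659
TM_INTERCEPT = 0.477
TM_ESTIMATE_RMSD = 0.084
CONTACT_SATISFIED_DISTANCE = 8.0
LONG_RANGE_SEPARATION = 24
SCORE_FLOOR = 1e-6


@dataclass(frozen=True)
class ConfidenceReport:
    nf: float
    sr: float
    dc: float
    c_score: float
    tm_estimate: float
    tm_uncertainty: float = TM_ESTIMATE_RMSD

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def satisfaction_rate(model: ChainConformation, cs: ConsensusContactSet,
                      top: int | None = None,
                      threshold: float = CONTACT_SATISFIED_DISTANCE) -> float:
    """Weighted satisfaction rate of the top-L long-range contacts.

    Sr = (1/n_L) sum delta_i w_i^2 with delta_i = 1 when the Cβ distance is
    within ``threshold`` and w_i = U_ij. ``top`` defaults to the chain
    length. Returns 0 (with a warning) when no long-range contact exists.
    """
    top = model.n_res if top is None else top
    lr = long_range_subset(cs, top, min_separation=LONG_RANGE_SEPARATION)
    if len(lr) == 0:
        warnings.warn("no long-range contacts available; Sr set to 0",
                      stacklevel=2)
        return 0.0
    idx_i = np.array([c.i - 1 for c in lr.contacts])
    idx_j = np.array([c.j - 1 for c in lr.contacts])
    if idx_j.max() >= model.n_res:
        raise IndexError("contact index exceeds model length")
    w = np.array([c.u for c in lr.contacts])
    d = np.linalg.norm(model.cb[idx_i] - model.cb[idx_j], axis=1)
    delta = (d <= threshold).astype(float)
    return float((delta * w ** 2).mean())


def c_score(nf: float, sr: float, dc: float) -> float:
    """Folding confidence 0.2 * ln(Nf) + ln(Sr * Dc).

    Zero Sr or Dc (a failed run) is floored at 1e-6 with a warning so the
    score stays finite.
    """
    if nf <= 0:
        raise ValueError("nf must be positive")
    if sr < 0 or dc < 0:
        raise ValueError("sr and dc must be non-negative")
    if sr < SCORE_FLOOR or dc < SCORE_FLOOR:
        warnings.warn("Sr or Dc at floor value; confidence is unreliable",
                      stacklevel=2)
    sr = max(sr, SCORE_FLOOR)
    dc = max(dc, SCORE_FLOOR)
    return float(0.2 * np.log(nf) + np.log(sr * dc))


def estimate_tm(c: float) -> tuple[float, float]:
    """Estimated TM-score from the linear calibration, clamped to [0, 1];
    the second element is the calibration's residual RMSD."""
    tm = TM_SLOPE * c + TM_INTERCEPT
    return float(np.clip(tm, 0.0, 1.0)), TM_ESTIMATE_RMSD


def _tm_d0(L: int) -> float:
    if L <= 15:
        return 0.5
    return max(1.24 * (L - 15) ** (1.0 / 3.0) - 1.8, 0.5)


def tm_score(model: ChainConformation, reference: ChainConformation,
             seed_step: int | None = None) -> float:
    """Length-normalised structural similarity in (0, 1].

    Heuristic search: rigid superpositions seeded on sliding windows of
    several lengths, each refined by iteratively re-superposing on the
    residues currently within the distance cutoff; the best score is kept.
    """
    if model.n_res != reference.n_res:
        raise ValueError("TM-score requires equal-length chains")
    L = model.n_res
    d0 = _tm_d0(L)
    mob = model.ca
    ref = reference.ca

    def score_from(d2: np.ndarray) -> float:
        return float(np.mean(1.0 / (1.0 + d2 / d0 ** 2)))

    best = 0.0
    window_lengths = sorted({4, max(4, L // 4), max(4, L // 2), L})
    for wlen in window_lengths:
        if wlen > L:
            continue
        step = seed_step or max(1, wlen // 2)
        for start in range(0, L - wlen + 1, step):
            sel = np.arange(start, start + wlen)
            for _ in range(20):
                # transform the full chain with the window's fit
                _, _, R, t = superpose(mob[sel], ref[sel])
                allmoved = mob @ R.T + t
                d2 = ((allmoved - ref) ** 2).sum(axis=1)
                best = max(best, score_from(d2))
                cutoff = d0
                new_sel = np.nonzero(d2 < cutoff ** 2)[0]
                while len(new_sel) < 3:
                    cutoff += 0.5
                    new_sel = np.nonzero(d2 < cutoff ** 2)[0]
                if np.array_equal(new_sel, sel):
                    break
                sel = new_sel
    return best


def calibration_check(pairs) -> tuple[float, float]:
    """Pearson correlation of (C-score, true TM) pairs and residual RMSD
    against the linear calibration."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need at least 3 (c_score, tm) pairs")
    c, tm = arr[:, 0], arr[:, 1]
    if np.std(c) < 1e-12 or np.std(tm) < 1e-12:
        raise ValueError("degenerate variance in calibration data")
    pearson = float(stats.pearsonr(c, tm).statistic)
    resid = tm - (TM_SLOPE * c + TM_INTERCEPT)
    return pearson, float(np.sqrt(np.mean(resid ** 2)))


def confidence_report(nf: float, sr: float, dc: float) -> ConfidenceReport:
    c = c_score(nf, sr, dc)
    tm, unc = estimate_tm(c)
    return ConfidenceReport(nf=nf, sr=sr, dc=dc, c_score=c,
                            tm_estimate=tm, tm_uncertainty=unc)
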