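"""Shared synthetic-benchmark machinery for the acceptance suite and the
acceptance report script."""
import warnings

import numpy as np

from contactfold.contact_consensus import build_consensus
from contactfold.decoy_analysis import (convergence_density,
                                        select_first_model, spicker_cluster)
from contactfold.folding_engine import (SimulationConfig,
                                        build_distance_profile, run_folding)
from contactfold.quality_score import (c_score, satisfaction_rate, tm_score)
from contactfold.toygen import (CorruptionSpec, ToySpec, corrupt_contacts,
                                make_fragment_library, make_toy_structure,
                                true_contacts)

FOLD_WEIGHTS = {"contact": 2.0, "bond": 1.0, "clash": 5.0, "profile": 0.4}


def local_profiles(frags, n_res, max_separation=12):
    return [
        p for p in (build_distance_profile(frags, i, j)
                    for i in range(n_res)
                    for j in range(i + 2, min(i + max_separation + 1,
                                              n_res)))
        if not p.is_empty
    ]


def fold_toy_target(topology, n_res, struct_seed, fold_seed, precision,
                    jitter, nf, n_replicas=5, steps=2000,
                    frag_lengths=tuple(range(3, 10)), max_profile_sep=6,
                    contact_weight=3.0):
    """Generate a corrupted synthetic target, fold it, and score the first
    model. Returns a dict of per-target outcomes."""
    conf = make_toy_structure(ToySpec(topology, n_res, seed=struct_seed))
    truth = true_contacts(conf)
    predictors = [
        corrupt_contacts(truth,
                         CorruptionSpec(precision, "very_high", 0.02,
                                        struct_seed * 100 + k), n_res)
        for k in (1, 2, 3)
    ]
    cs = build_consensus(predictors, n_res, nf=nf)
    frags = make_fragment_library(conf, lengths=frag_lengths,
                                  per_position=8, jitter=jitter,
                                  seed=struct_seed)
    profiles = local_profiles(frags, n_res, max_profile_sep)
    weights = dict(FOLD_WEIGHTS)
    weights["contact"] = contact_weight
    config = SimulationConfig(seed=fold_seed, n_replicas=n_replicas,
                              steps_per_replica=steps, swap_interval=100,
                              t_min=0.4, t_max=5.0, weights=weights)
    ensemble = run_folding(conf.sequence, cs, frags, config,
                           profiles=profiles)
    solutions = spicker_cluster(ensemble)
    model = select_first_model(solutions, ensemble)
    top = max(solutions, key=lambda s: s.M)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sr = satisfaction_rate(model, cs)
        dc = convergence_density(top, ensemble.M_tot)
        c = c_score(nf, sr, dc)

    lr = [ct for ct in truth.contacts if ct.separation > 24]
    if lr:
        d = np.array([np.linalg.norm(model.cb[ct.i - 1] - model.cb[ct.j - 1])
                      for ct in lr])
        true_lr_satisfaction = float((d <= 8.0).mean())
    else:
        true_lr_satisfaction = float("nan")
    return {
        "native": conf,
        "model": model,
        "sr": sr,
        "dc": dc,
        "c_score": c,
        "tm": tm_score(model, conf),
        "true_lr_satisfaction": true_lr_satisfaction,
        "n_long_range_true": len(lr),
    }


def calibration_benchmark(n_targets, seed, **fold_kwargs):
    """Folding benchmark across alignment-depth tiers: deeper synthetic
    families get more precise contacts and cleaner fragments, mirroring how
    prediction quality scales with effective alignment depth."""
    topologies = ["helix_bundle", "beta_hairpin", "mixed"]
    rng = np.random.default_rng(seed)
    results = []
    for k in range(n_targets):
        topology = topologies[k % 3]
        # below ~46 residues some topologies carry almost no long-range
        # contacts, which degenerates Sr; keep targets in the upper band
        n_res = int(rng.integers(46, 61))
        nf = float(np.exp(rng.uniform(np.log(15), np.log(300))))
        quality = (np.log(nf) - np.log(15)) / (np.log(300) - np.log(15))
        precision = float(np.clip(0.2 + 0.65 * quality
                                  + rng.normal(0, 0.05), 0.15, 0.9))
        jitter = float(np.clip(0.8 - 0.72 * quality
                               + rng.normal(0, 0.05), 0.05, 0.9))
        outcome = fold_toy_target(
            topology, n_res, struct_seed=seed * 1000 + k,
            fold_seed=seed * 2000 + k, precision=precision, jitter=jitter,
            nf=nf, **fold_kwargs)
        outcome.update(topology=topology, n_res=n_res, nf=nf,
                       precision=precision, jitter=jitter)
        results.append(outcome)
    return results
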