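import numpy as np
import pytest

from contactfold.folding_engine import (ChainConformation, DecoyEnsemble,
                                        EnergyModel,
                                        FragmentLibrary, SimulationConfig,
                                        build_distance_profile,
                                        extended_chain, metropolis_accept,
                                        propose_move, replica_exchange_sweep,
                                        run_folding, total_energy)
from contactfold.folding_engine import _fragment_substitution
from contactfold.geometry import (rotate_about_axis, validate_chain,
                                  virtual_cb)
from contactfold.toygen import random_walk_chain


# -- conformations --------------------------------------------------------


def test_conformation_builds_virtual_cb():
    conf = extended_chain("ACDEFGHIKL")
    assert conf.cb.shape == (10, 3)
    # interior virtual cb sits at the fixed bond length from its ca
    d = np.linalg.norm(conf.cb[1:-1] - conf.ca[1:-1], axis=1)
    assert np.allclose(d, 1.53)


def test_conformation_shape_mismatch():
    with pytest.raises(ValueError):
        ChainConformation("ACD", np.zeros((4, 3)))


def test_extended_chain_is_valid():
    extended_chain("A" * 80).validate()


# -- distance profiles ----------------------------------------------------


def _library_from_segments(segments, n_res, start=0):
    return FragmentLibrary({start: [np.asarray(s, float) for s in segments]},
                           n_res=n_res, top_n=max(200, len(segments)))


def test_profile_single_bin():
    seg = extended_chain("AAAAAA").ca
    frags = _library_from_segments([seg.copy() for _ in range(200)], 6)
    profile = build_distance_profile(frags, 1, 4)
    assert profile.n_obs == 200
    assert (profile.counts > 0).sum() == 1


def test_profile_empty_when_uncovered():
    seg = extended_chain("AAAA").ca
    frags = _library_from_segments([seg], 20)
    profile = build_distance_profile(frags, 10, 15)
    assert profile.is_empty
    assert profile.energy(5.0) == 0.0


def test_profile_matches_naive_tally(rng):
    segments = [random_walk_chain(8, seed=s).ca for s in range(15)]
    frags = _library_from_segments(segments, 8)
    i, j = 1, 6
    profile = build_distance_profile(frags, i, j, bin_width=0.5)
    expected = np.zeros_like(profile.counts)
    for seg in segments:
        cb = virtual_cb(seg)
        d = float(np.linalg.norm(cb[i] - cb[j]))
        expected[min(int(d / 0.5), len(expected) - 1)] += 1
    assert np.array_equal(profile.counts, expected)


def test_profile_mass_invariant(rng):
    segments = [random_walk_chain(10, seed=s).ca for s in range(7)]
    frags = _library_from_segments(segments, 10)
    profile = build_distance_profile(frags, 0, 9)
    assert profile.n_obs == 7


# -- total energy ---------------------------------------------------------


def test_ideal_chain_has_negligible_generic_terms():
    conf = extended_chain("A" * 30)
    model = EnergyModel(30, None)
    terms = model.terms(conf)
    assert terms["contact"] == 0.0
    assert terms["bond"] < 0.5   # 3.7 vs 3.8 ideal bond
    assert terms["clash"] == pytest.approx(0.0)


def test_clash_penalty_sign():
    ca = extended_chain("A" * 10).ca.copy()
    ca[5] = ca[3] + np.array([1.0, 0.0, 0.0])
    conf = ChainConformation("A" * 10, ca)
    model = EnergyModel(10, None)
    assert model.clash_term(conf) > 0


def test_total_energy_is_sum_of_terms(hairpin40, hairpin40_consensus,
                                      hairpin40_frags):
    profiles = [build_distance_profile(hairpin40_frags, i, i + 4)
                for i in range(0, 30, 5)]
    model = EnergyModel(40, hairpin40_consensus, profiles=profiles)
    terms = model.terms(hairpin40)
    assert model.total(hairpin40) == pytest.approx(sum(terms.values()))
    assert total_energy(hairpin40, hairpin40_consensus,
                        profiles=profiles) == pytest.approx(
        model.total(hairpin40))


def test_energy_model_rejects_out_of_range_contacts(hairpin40_consensus):
    with pytest.raises(IndexError):
        EnergyModel(10, hairpin40_consensus)


# -- moves ----------------------------------------------------------------


def test_identity_fragment_substitution_preserves_chain():
    conf = extended_chain("A" * 20)
    frags = FragmentLibrary({4: [conf.ca[4:11].copy()]}, n_res=20)
    rng = np.random.default_rng(0)
    new_ca = _fragment_substitution(conf.ca, frags, rng)
    assert np.allclose(new_ca, conf.ca, atol=1e-9)


def test_zero_angle_rotation_is_identity(rng):
    pts = rng.normal(size=(12, 3))
    out = rotate_about_axis(pts, pts[0], np.array([0.0, 0.0, 1.0]), 0.0)
    assert np.allclose(out, pts)


def test_propose_move_deterministic(hairpin40, hairpin40_frags):
    def trajectory(seed):
        rng = np.random.default_rng(seed)
        conf = hairpin40.copy()
        out = []
        for _ in range(25):
            conf = propose_move(conf, hairpin40_frags, rng)
            out.append(conf.ca.copy())
        return out

    a = trajectory(99)
    b = trajectory(99)
    for x, y in zip(a, b):
        assert np.array_equal(x, y)


def test_propose_move_respects_invariants(hairpin40, hairpin40_frags):
    rng = np.random.default_rng(5)
    conf = hairpin40.copy()
    for _ in range(60):
        conf = propose_move(conf, hairpin40_frags, rng)
        validate_chain(conf.ca)


def test_propose_move_without_fragments(hairpin40):
    rng = np.random.default_rng(5)
    conf = propose_move(hairpin40, None, rng)
    validate_chain(conf.ca)


# -- Metropolis and replica exchange --------------------------------------


def test_metropolis_always_accepts_downhill(rng):
    assert metropolis_accept(-5.0, 1.0, rng)
    assert metropolis_accept(0.0, 1.0, rng)


def test_metropolis_never_accepts_infinite(rng):
    assert not metropolis_accept(np.inf, 1.0, rng)


def test_metropolis_empirical_rate():
    rng = np.random.default_rng(7)
    t = 1.7
    delta = t * np.log(2.0)
    accepted = sum(metropolis_accept(delta, t, rng) for _ in range(10_000))
    assert accepted / 10_000 == pytest.approx(0.5, abs=0.02)


def test_metropolis_rejects_bad_temperature(rng):
    with pytest.raises(ValueError):
        metropolis_accept(1.0, 0.0, rng)


def test_swap_accepts_equal_energies(rng):
    conf = extended_chain("AAAA")
    replicas = [[conf.copy(), 5.0, 1.0], [conf.copy(), 5.0, 2.0]]
    a_before = replicas[0][0]
    replica_exchange_sweep(replicas, rng)
    assert replicas[1][0] is a_before  # swap happened with probability 1


def test_swap_requires_increasing_ladder(rng):
    conf = extended_chain("AAAA")
    replicas = [[conf.copy(), 1.0, 2.0], [conf.copy(), 1.0, 1.0]]
    with pytest.raises(ValueError):
        replica_exchange_sweep(replicas, rng)


def test_swap_rate_matches_closed_form():
    rng = np.random.default_rng(11)
    t_a, t_b = 1.0, 2.0
    e_a, e_b = 3.0, 1.0
    expected = min(1.0, np.exp((1 / t_a - 1 / t_b) * (e_a - e_b)))
    conf = extended_chain("AAAA")
    swaps = 0
    trials = 10_000
    for _ in range(trials):
        replicas = [[conf, e_a, t_a], [conf, e_b, t_b]]
        replica_exchange_sweep(replicas, rng)
        swaps += replicas[0][1] == e_b
    assert swaps / trials == pytest.approx(expected, abs=0.02)


def test_two_state_boltzmann_sanity():
    """Metropolis dynamics on a two-state discretization reproduces the
    Boltzmann ratio within 3 sigma."""
    rng = np.random.default_rng(3)
    energies = {0: 0.0, 1: 1.2}
    t = 1.0
    state = 0
    counts = np.zeros(2)
    n = 40_000
    for _ in range(n):
        other = 1 - state
        if metropolis_accept(energies[other] - energies[state], t, rng):
            state = other
        counts[state] += 1
    p1 = np.exp(-energies[1] / t) / (1 + np.exp(-energies[1] / t))
    sigma = np.sqrt(p1 * (1 - p1) / n) * 12  # generous correlated-sample factor
    assert counts[1] / n == pytest.approx(p1, abs=3 * sigma)


# -- run_folding ----------------------------------------------------------


def _tiny_config(seed=1, steps=200):
    return SimulationConfig(seed=seed, n_replicas=3, t_min=0.5, t_max=3.0,
                            steps_per_replica=steps, swap_interval=50,
                            snapshot_interval=50)


def test_zero_steps_yields_initial_conformation(hairpin40_consensus):
    cfg = SimulationConfig(seed=1, n_replicas=2, steps_per_replica=0)
    ens = run_folding("A" * 40, hairpin40_consensus, None, cfg)
    assert ens.M_tot == 1
    assert np.allclose(ens.decoys[0].ca, extended_chain("A" * 40).ca)


def test_run_folding_deterministic(hairpin40_consensus, hairpin40_frags):
    seq = "A" * 40
    e1 = run_folding(seq, hairpin40_consensus, hairpin40_frags,
                     _tiny_config())
    e2 = run_folding(seq, hairpin40_consensus, hairpin40_frags,
                     _tiny_config())
    assert e1.M_tot == e2.M_tot
    for a, b in zip(e1.decoys, e2.decoys):
        assert np.array_equal(a.ca, b.ca)
    assert e1.energies == e2.energies


def test_run_folding_decoys_satisfy_geometry(hairpin40_consensus,
                                             hairpin40_frags):
    ens = run_folding("A" * 40, hairpin40_consensus, hairpin40_frags,
                      _tiny_config(seed=9))
    for decoy in ens.decoys:
        validate_chain(decoy.ca)


def test_run_folding_writes_trajectory_log(tmp_path, hairpin40_consensus):
    log = tmp_path / "traj.tsv"
    run_folding("A" * 40, hairpin40_consensus, None,
                _tiny_config(steps=100), log_path=log)
    lines = log.read_text().strip().splitlines()
    assert lines[0].split("\t") == ["sweep", "replica", "temperature",
                                    "energy"]
    assert len(lines) > 1


def test_energy_bookkeeping_consistency(hairpin40_consensus, hairpin40_frags):
    """Accumulating per-move deltas reproduces a fresh full evaluation."""
    model = EnergyModel(40, hairpin40_consensus)
    rng = np.random.default_rng(17)
    conf = extended_chain("A" * 40)
    energy = model.total(conf)
    accepted = 0
    for _ in range(400):
        cand = propose_move(conf, hairpin40_frags, rng)
        if cand is conf:
            continue
        delta = model.total(cand) - model.total(conf)
        if metropolis_accept(delta, 1.0, rng):
            conf = cand
            energy += delta
            accepted += 1
    assert accepted > 10
    assert energy == pytest.approx(model.total(conf), abs=1e-6)


def test_simulation_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, n_replicas=0)
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, t_min=-1.0)
    with pytest.raises(ValueError):
        SimulationConfig(seed=1, steps_per_replica=-5)
    ladder = SimulationConfig(seed=1, n_replicas=5).temperature_ladder
    assert np.all(np.diff(ladder) > 0)


def test_decoy_ensemble_invariants():
    with pytest.raises(ValueError):
        DecoyEnsemble(decoys=[], energies=[])
    conf = extended_chain("AAAA")
    with pytest.raises(ValueError):
        DecoyEnsemble(decoys=[conf], energies=[1.0, 2.0])
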