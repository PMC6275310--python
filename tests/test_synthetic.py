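"""Transitivity-targeted network generation and noisy report simulation."""

import dataclasses
import math

import numpy as np
import pytest

from scmnet import (
    evolve_network,
    expand_report,
    generate_true_network,
    simulate_model_table,
    simulate_report,
    simulate_study,
    transitivity_index,
)
from scmnet.io import Roster
from scmnet.synthetic import (
    SimulationConfig,
    TransitivityTargetError,
    _random_graph,
)


class TestGenerateTrueNetwork:
    @pytest.mark.parametrize("target", [0.3, 0.6])
    def test_reaches_target_within_tolerance(self, target):
        net = generate_true_network(20, 0.2, target, tol=0.02, seed=1)
        # verified by the independent metrics-module computation
        assert abs(transitivity_index(net) - target) <= 0.02
        assert net.n_edges == round(0.2 * 20 * 19 / 2)

    def test_deterministic_given_seed(self):
        a = generate_true_network(20, 0.2, 0.5, tol=0.02, seed=7)
        b = generate_true_network(20, 0.2, 0.5, tol=0.02, seed=7)
        assert a == b

    def test_target_equal_to_initial_returns_immediately(self):
        rng = np.random.default_rng(3)
        nodes = [f"m{i:02d}" for i in range(20)]
        initial = _random_graph(nodes, round(0.2 * 190), rng)
        import networkx as nx

        target = nx.transitivity(initial)
        net = generate_true_network(20, 0.2, target, tol=0.02, seed=3, max_iter=0)
        assert set(net.edges) == {tuple(sorted(e)) for e in initial.edges()}

    def test_unreachable_target_reports_best(self):
        with pytest.raises(TransitivityTargetError, match="best achieved") as exc:
            generate_true_network(20, 0.2, 1.0, tol=0.001, seed=1, max_iter=50)
        assert 0.0 <= exc.value.best <= 1.0

    def test_zero_edges_rejected(self):
        with pytest.raises(ValueError, match="zero edges"):
            generate_true_network(20, 0.0, 0.5, seed=1)


class TestEvolveNetwork:
    def test_identity_when_nothing_to_do(self):
        net = generate_true_network(20, 0.2, 0.5, tol=0.02, seed=2)
        same = evolve_network(net, 0.0, transitivity_index(net), tol=0.02, seed=9)
        assert same == net

    def test_full_rewire_hits_new_target(self):
        net = generate_true_network(20, 0.2, 0.4, tol=0.02, seed=2)
        evolved = evolve_network(net, 1.0, 0.6, tol=0.02, seed=9)
        assert abs(transitivity_index(evolved) - 0.6) <= 0.02
        assert evolved.n_edges == net.n_edges

    def test_deterministic_given_seed(self):
        net = generate_true_network(20, 0.2, 0.4, tol=0.02, seed=2)
        a = evolve_network(net, 0.3, 0.5, tol=0.02, seed=11)
        b = evolve_network(net, 0.3, 0.5, tol=0.02, seed=11)
        assert a == b


class TestSimulateReport:
    def _config(self, **kw):
        defaults = dict(p_hit_own=1.0, p_hit_other=1.0, p_false=0.0, coupling=None)
        defaults.update(kw)
        return SimulationConfig(**defaults)

    def test_noiseless_limit_reproduces_truth(self):
        true = generate_true_network(15, 0.2, 0.5, tol=0.05, seed=4)
        report = simulate_report(true, sorted(true.nodes)[0], self._config(), 0.5, seed=1)
        roster = Roster("c", 0, true.nodes, true.nodes)
        assert expand_report(report, roster) == true

    def test_blind_perceiver_reports_all_isolates(self):
        true = generate_true_network(15, 0.2, 0.5, tol=0.05, seed=4)
        cfg = self._config(p_hit_own=0.0, p_hit_other=0.0)
        report = simulate_report(true, sorted(true.nodes)[0], cfg, 0.5, seed=1)
        assert report.groups == ()
        assert report.isolates == true.nodes

    def test_coupling_raises_coverage_with_transitivity(self):
        """With a positive coupling slope, perceivers in more transitive
        classrooms report a larger share of true ties (expected coverage
        equals the hit probability; compare Monte-Carlo means)."""
        cfg = SimulationConfig(p_hit_own=1.0, p_false=0.0, coupling=(-1.3, 3.2))
        true = generate_true_network(20, 0.2, 0.5, tol=0.05, seed=8)
        perceiver = sorted(true.nodes)[0]
        roster = Roster("c", 0, true.nodes, true.nodes)

        def mean_coverage(t_class, seeds):
            covs = []
            for s in seeds:
                rep = simulate_report(true, perceiver, cfg, t_class, seed=s)
                net = expand_report(rep, roster)
                covs.append(len(net.edges & true.edges) / len(true.edges))
            return float(np.mean(covs))

        low = mean_coverage(0.3, range(80))
        high = mean_coverage(0.8, range(80))
        assert high > low
        # expected coverage ~ mix of own-tie (1.0) and other-tie hit rates
        def expect(t):
            p_other = 1 / (1 + math.exp(-(-1.3 + 3.2 * t)))
            deg = sum(1 for e in true.edges if perceiver in e)
            other = len(true.edges) - deg
            return (deg * 1.0 + other * p_other) / len(true.edges)

        assert low == pytest.approx(expect(0.3), abs=0.05)
        assert high == pytest.approx(expect(0.8), abs=0.05)

    def test_unknown_perceiver_rejected(self):
        true = generate_true_network(10, 0.2, 0.3, tol=0.1, seed=4)
        with pytest.raises(ValueError, match="not in the network"):
            simulate_report(true, "stranger", self._config(), 0.5, seed=0)


class TestSimulateStudy:
    def test_files_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(n_classrooms=2, n_waves=2, seed=21)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_study(cfg, out_dir=d1)
        simulate_study(cfg, out_dir=d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_planted_transitivity_matches_metrics_module(self):
        cfg = SimulationConfig(n_classrooms=2, n_waves=2, seed=5)
        study = simulate_study(cfg)
        for key, net in study.planted.items():
            assert study.planted_transitivity[key] == pytest.approx(transitivity_index(net))

    def test_probability_validation(self):
        with pytest.raises(ValueError, match="p_hit_own"):
            SimulationConfig(p_hit_own=1.5)
        with pytest.raises(ValueError, match="rewire_fraction"):
            SimulationConfig(rewire_fraction=-0.1)


class TestPlantedCouplingRecovery:
    def test_within_person_effect_recovered_across_replicates(self):
        """With the logistic transitivity->hit-rate coupling enabled, the
        fitted within-person transitivity effect is positive in nearly every
        replicate study and centred near the planted translation (~0.4)."""
        from scmnet.longitudinal import fit_random_intercept
        from scmnet.pipeline import analyze_classroom_waves

        estimates = []
        for seed in range(10):
            cfg = SimulationConfig(n_classrooms=8, seed=seed)
            study = simulate_study(cfg)
            *_, table, _ = analyze_classroom_waves(
                list(study.rosters), {k: list(v) for k, v in study.reports.items()}
            )
            fit = fit_random_intercept(table)
            estimates.append(fit.coefficient("transitivity_change").estimate)
        assert sum(e > 0 for e in estimates) >= 8
        assert 0.2 <= float(np.mean(estimates)) <= 0.6


class TestSimulateModelTable:
    def test_change_zero_at_first_wave(self):
        table = simulate_model_table(n_participants=30, seed=2)
        first = table[table.wave_id == 0]
        assert (first.transitivity_change == 0).all()

    def test_reproducible(self):
        a = simulate_model_table(n_participants=20, seed=3)
        b = simulate_model_table(n_participants=20, seed=3)
        assert a.equals(b)
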