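"""Planted-activity simulator, input-list derivation, ROC and PPV harness."""

import numpy as np
import pandas as pd
import pytest

from mitena import generate_synthetic_db
from mitena import simulation as sim
from tests.conftest import make_db


@pytest.fixture(scope="module")
def small_db():
    return generate_synthetic_db(60, 2000, exponent=1.8, min_targets=20,
                                 max_targets=400, seed=5)


def tiny_config(**kw):
    defaults = dict(n_samples=40, n_affected=20, n_active=2,
                    target_counts=(50, 100), alpha_grid=(0.5,), seed=1)
    defaults.update(kw)
    return sim.SimulationConfig(**defaults)


class TestConfig:
    def test_budget_list_must_match_n_active(self):
        with pytest.raises(ValueError):
            sim.SimulationConfig(n_active=3, target_counts=(100, 200))

    def test_affected_cannot_exceed_samples(self):
        with pytest.raises(ValueError):
            sim.SimulationConfig(n_samples=10, n_affected=20,
                                 n_active=1, target_counts=(100,))

    def test_reference_defaults(self):
        cfg = sim.SimulationConfig()
        assert cfg.n_samples == 100 and cfg.n_affected == 50 and cfg.n_active == 10
        assert cfg.target_counts == tuple(range(100, 1001, 100))
        assert len(cfg.alpha_grid) == 15
        assert cfg.alpha_grid[0] == pytest.approx(0.3)
        assert cfg.alpha_grid[-1] == pytest.approx(1.0)


class TestSimulateExpression:
    def test_same_seed_identical_matrices(self, small_db):
        cfg = tiny_config()
        a = sim.simulate_expression(cfg, small_db, alpha=0.5, seed=9)
        b = sim.simulate_expression(cfg, small_db, alpha=0.5, seed=9)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        assert a.active_mirnas == b.active_mirnas

    def test_background_is_standard_normal(self, small_db):
        cfg = tiny_config()
        ds = sim.simulate_expression(cfg, small_db, alpha=0.5, seed=2)
        quiet = ds.expression.drop(index=list(ds.repressed_genes))
        vals = quiet.to_numpy().ravel()
        assert vals.mean() == pytest.approx(0.0, abs=0.02)
        assert vals.var() == pytest.approx(1.0, abs=0.03)

    def test_repressed_targets_shifted_in_affected_samples_only(self, small_db):
        cfg = tiny_config()
        ds = sim.simulate_expression(cfg, small_db, alpha=1.0, seed=3)
        rep = ds.expression.loc[sorted(ds.repressed_genes)]
        aff = rep[ds.affected_samples].to_numpy().ravel()
        unaff = rep[ds.unaffected_samples].to_numpy().ravel()
        assert aff.mean() < -0.7          # expectation -alpha = -1
        assert abs(unaff.mean()) < 0.1    # untouched

    def test_no_eligible_mirna_for_budget(self, small_db):
        cfg = tiny_config(target_counts=(50, 1500))  # nobody has 1500 targets
        with pytest.raises(ValueError, match="active"):
            sim.simulate_expression(cfg, small_db, alpha=0.5)


class TestDeriveInputList:
    def test_high_activity_recalls_planted_targets(self, small_db):
        cfg = tiny_config(n_samples=100, n_affected=50)
        ds = sim.simulate_expression(cfg, small_db, alpha=1.0, seed=4)
        found = set(sim.derive_input_list(ds))
        recall = len(found & ds.repressed_genes) / len(ds.repressed_genes)
        assert recall > 0.9

    def test_null_data_yields_almost_no_genes(self, small_db):
        # no planted effect at all: BH at 5% on pure noise
        rng = np.random.default_rng(8)
        genes = small_db.genes
        samples = [f"S{i:03d}" for i in range(100)]
        ds = sim.SimulatedDataset(
            expression=pd.DataFrame(rng.standard_normal((len(genes), 100)),
                                    index=genes, columns=samples),
            active_mirnas=[], affected_samples=samples[:50], alpha=0.3,
        )
        assert len(sim.derive_input_list(ds)) / len(genes) < 0.01

    def test_deterministic_given_dataset(self, small_db):
        ds = sim.simulate_expression(tiny_config(), small_db, alpha=0.8, seed=6)
        assert sim.derive_input_list(ds) == sim.derive_input_list(ds)

    def test_degenerate_groups_rejected(self, small_db):
        cfg = tiny_config()
        ds = sim.simulate_expression(cfg, small_db, alpha=0.5, seed=1)
        ds.affected_samples = ds.expression.columns[:-1].tolist()  # 1 control left
        with pytest.raises(ValueError):
            sim.derive_input_list(ds)


class TestRocAuc:
    def test_perfect_detector_has_unit_area(self):
        points = [(a, 0.0, 1.0) for a in (0.3, 0.5, 1.0)]
        assert sim.roc_auc(points) == pytest.approx(1.0)

    def test_no_discrimination_diagonal(self):
        points = [(a, r, r) for a, r in [(0.3, 0.2), (0.5, 0.5), (1.0, 0.8)]]
        assert sim.roc_auc(points) == pytest.approx(0.5)

    def test_invariant_to_point_order(self):
        rng = np.random.default_rng(13)
        points = [(a, float(f), float(t)) for a, f, t in
                  zip(np.linspace(0.3, 1, 8), rng.uniform(size=8), rng.uniform(size=8))]
        shuffled = list(points)
        rng.shuffle(shuffled)
        assert sim.roc_auc(points) == pytest.approx(sim.roc_auc(shuffled))


class TestEvaluateDetection:
    def test_power_increases_with_activity(self, small_db):
        # planted effects are easier to see at alpha=1.0 than at 0.3
        tprs = {0.3: [], 1.0: []}
        for seed in range(10):
            cfg = tiny_config(n_samples=60, n_affected=30, alpha_grid=(0.3, 1.0),
                              seed=seed)
            res = sim.evaluate_detection(small_db, cfg)
            for alpha, fpr, tpr in res.points:
                tprs[alpha].append(tpr)
        assert np.mean(tprs[1.0]) >= np.mean(tprs[0.3])

    def test_detected_sets_and_points_align(self, small_db):
        cfg = tiny_config(seed=3)
        res = sim.evaluate_detection(small_db, cfg)
        (alpha, fpr, tpr), = res.points
        active = set(res.active_mirnas)
        detected = res.detected[alpha]
        assert tpr == len(detected & active) / len(active)
        assert 0 <= fpr <= 1


class TestRepresentativeMirnas:
    def test_percentile_selection_matches_quantile_convention(self):
        profile = pd.Series({f"m{i}": float(i) for i in range(1, 101)})
        chosen = sim.select_representative_mirnas(profile, percentile=75)
        # linear-interpolation 75th percentile of 1..100 is 75.25
        assert chosen == {f"m{i}" for i in range(76, 101)}

    def test_all_equal_selects_nothing(self):
        profile = pd.Series({"a": 2.0, "b": 2.0, "c": 2.0})
        assert sim.select_representative_mirnas(profile) == set()

    def test_repeats_averaged_before_thresholding(self):
        df = pd.DataFrame({"mirna": ["a", "a", "b", "c", "d"],
                           "expression": [0.0, 10.0, 1.0, 2.0, 3.0]})
        averaged = sim.average_repeat_measurements(df)
        assert averaged["a"] == pytest.approx(5.0)
        chosen = sim.select_representative_mirnas(averaged, percentile=75)
        assert chosen == {"a"}  # 75th pct of {5,1,2,3} is 3.5

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            sim.select_representative_mirnas(pd.Series(dtype=float))


class TestPpvEvaluation:
    @pytest.fixture
    def two_mirna_db(self):
        pairs = ([("miR-A", f"G{i}") for i in range(10)]
                 + [("miR-B", f"H{i}") for i in range(10)])
        return make_db(pairs, scores=[-0.5] * 20)

    def test_perfect_reference_gives_unit_ppv(self, two_mirna_db):
        res = sim.ppv_evaluation([f"G{i}" for i in range(10)], {"miR-A"}, two_mirna_db)
        assert res.detected == {"miR-A"}
        assert (res.tp, res.fp) == (1, 0)
        assert res.ppv == 1.0

    def test_wrong_reference_gives_zero_ppv(self, two_mirna_db):
        res = sim.ppv_evaluation([f"G{i}" for i in range(10)], {"miR-B"}, two_mirna_db)
        assert (res.tp, res.fp) == (0, 1)
        assert res.ppv == 0.0

    def test_nothing_detected_is_undefined_not_crash(self, two_mirna_db):
        # a single gene from each miRNA: no enrichment survives the filter
        res = sim.ppv_evaluation(["G0"], {"miR-A"}, two_mirna_db)
        if not res.detected:
            assert res.ppv is None and not res.defined

    def test_empty_inputs_rejected(self, two_mirna_db):
        with pytest.raises(ValueError):
            sim.ppv_evaluation([], {"miR-A"}, two_mirna_db)
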