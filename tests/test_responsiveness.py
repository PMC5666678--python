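"""Threshold classification rules: boundaries, oracles, truth recovery."""

import numpy as np
import pandas as pd
import pytest

from stimseq import responsiveness as rp
from stimseq import simulate


def make_table(rows):
    """rows: (feature_id, fpkm_vehicle, fpkm_egf, fold_change, q_value)."""
    return pd.DataFrame(
        rows, columns=["feature_id", "fpkm_vehicle", "fpkm_egf", "fold_change", "q_value"]
    )


class TestFoldInduction:
    def test_arithmetic(self):
        assert rp.fold_induction(2, 8, 0.1) == pytest.approx(8.1 / 2.1)

    def test_empty_empty_identity(self):
        assert rp.fold_induction(0, 0, 1e-6) == pytest.approx(1.0)

    def test_equal_inputs_give_unity(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, size=50)
        assert rp.fold_induction(x, x, 0.1) == pytest.approx(np.ones(50))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            rp.fold_induction(-1, 5, 0.1)
        with pytest.raises(ValueError):
            rp.fold_induction(1, 5, 0)


class TestResponsiveGenes:
    def test_all_thresholds_passed(self):
        table = make_table([("g", 1.0, 5.0, 3.0, 0.01)])
        calls = rp.call_responsive_genes(table, "vehicle", "egf")
        assert list(calls["feature_id"]) == ["g"]

    @pytest.mark.parametrize(
        "fold, q, fpkm",
        [
            (3.0, 0.06, 5.0),   # q above threshold
            (3.0, 0.05, 5.0),   # q exactly at the boundary: strict
            (2.0, 0.01, 5.0),   # fold exactly at the boundary: strict
            (3.0, 0.01, 1.0),   # FPKM exactly at the boundary: strict
        ],
    )
    def test_boundaries_are_strict(self, fold, q, fpkm):
        table = make_table([("g", 1.0, fpkm, fold, q)])
        assert rp.call_responsive_genes(table, "vehicle", "egf").empty

    def test_erna_thresholds(self):
        table = make_table([("e1", 0.5, 0.6, 1.7, 0.01), ("e2", 1.0, 2.0, 1.5, 0.01)])
        calls = rp.call_responsive_ernas(table, "vehicle", "egf")
        assert list(calls["feature_id"]) == ["e1"]

    def test_ranking_is_descending_fold_induction_permutation(self):
        table = make_table(
            [("a", 1.0, 3.0, 3.0, 0.01), ("b", 1.0, 9.0, 9.0, 0.01), ("c", 1.0, 5.0, 5.0, 0.01)]
        )
        calls = rp.call_responsive_genes(table, "vehicle", "egf")
        assert list(calls["feature_id"]) == ["b", "c", "a"]
        assert sorted(calls["rank"]) == [1, 2, 3]

    def test_missing_column_is_schema_error(self):
        with pytest.raises(rp.SchemaError):
            rp.call_responsive_genes(
                make_table([("g", 1, 2, 2, 0.1)]).drop(columns=["q_value"]), "vehicle", "egf"
            )

    def test_recovers_planted_responsive_genes_noise_free(self):
        cfg = simulate.CohortConfig(seed=9, noise_sd=0.0)
        table = simulate.simulate_expression(cfg, "egf", features="genes")
        _, truth_fold, _ = simulate._expression_truth(cfg)
        responsive, _, _ = simulate._expression_truth(cfg)
        calls = rp.call_responsive_genes(table, "vehicle", "egf")
        assert set(calls["feature_id"]) == responsive
        # noise-free fold changes equal the planted inductions exactly
        for fid, fc in zip(table["feature_id"], table["fold_change"]):
            if fid in responsive:
                assert fc == pytest.approx(truth_fold[fid])

    def test_recovers_planted_induced_ernas_noise_free(self):
        cfg = simulate.CohortConfig(seed=9, noise_sd=0.0)
        table = simulate.simulate_expression(cfg, "egf", features="ernas")
        calls = rp.call_responsive_ernas(table, "vehicle", "egf")
        assert set(calls["feature_id"]) == set(table["feature_id"])
        assert len(calls) == cfg.n_planted_ernas

    def test_monotonic_in_thresholds(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            table = make_table(
                [
                    (f"g{i}", rng.uniform(0, 5), rng.uniform(0, 20),
                     rng.uniform(-5, 8), rng.uniform(0, 1))
                    for i in range(n)
                ]
            )
            base = set(rp.call_responsive_genes(table, "vehicle", "egf")["feature_id"])
            stricter_q = set(
                rp.call_responsive_genes(table, "vehicle", "egf", max_q=0.01)["feature_id"]
            )
            stricter_fold = set(
                rp.call_responsive_genes(table, "vehicle", "egf", min_fold=4.0)["feature_id"]
            )
            assert stricter_q <= base
            assert stricter_fold <= base

    def test_pure_function_of_inputs(self):
        table = make_table([("g", 1.0, 5.0, 3.0, 0.01), ("h", 1.0, 9.0, 9.0, 0.2)])
        a = rp.call_responsive_genes(table, "vehicle", "egf")
        b = rp.call_responsive_genes(table.copy(), "vehicle", "egf")
        pd.testing.assert_frame_equal(a, b)


class TestInhibitorResponsive:
    def tables(self, spec):
        """spec: feature -> list of signed folds per inhibitor arm."""
        arms = {}
        n_arms = len(next(iter(spec.values())))
        for i in range(n_arms):
            arms[f"inh{i}"] = make_table(
                [(f, 10.0, 10.0, folds[i], 0.01) for f, folds in spec.items()]
            )
        return arms

    def test_reduced_in_all_arms(self):
        arms = self.tables({"hit": [-3, -3, -3], "partial": [-3, -3, 1.0]})
        hits = rp.call_inhibitor_responsive(arms, "fpkm_vehicle")
        assert hits == {"hit"}

    def test_requires_two_tables(self):
        (only,) = self.tables({"x": [-3]}).values()
        with pytest.raises(rp.SchemaError):
            rp.call_inhibitor_responsive({"a": only}, "fpkm_vehicle")

    def test_matches_set_intersection_oracle_on_random_tables(self):
        rng = np.random.default_rng(55)
        for _ in range(50):
            feats = [f"g{i}" for i in range(20)]
            arms = {
                f"inh{a}": make_table(
                    [
                        (f, 10.0, 10.0, float(rng.uniform(-5, 5)), float(rng.uniform(0, 0.2)))
                        for f in feats
                    ]
                )
                for a in range(3)
            }
            expected = None
            for t in arms.values():
                s = {
                    r.feature_id
                    for r in t.itertuples()
                    if r.fold_change <= -2 and r.q_value < 0.05 and r.fpkm_vehicle > 1
                }
                expected = s if expected is None else expected & s
            assert rp.call_inhibitor_responsive(arms, "fpkm_vehicle") == expected


class TestControlSelection:
    def eligible_tables(self, n_eligible=12, n_bad=5):
        rows = [(f"ok{i}", 5.0, 5.0, 1.1, 0.5) for i in range(n_eligible)]
        rows += [(f"bad{i}", 5.0, 5.0, 3.0, 0.01) for i in range(n_bad)]
        return {"a": make_table(rows), "b": make_table(rows)}

    def test_deterministic_under_seed(self):
        tables = self.eligible_tables()
        a = rp.select_control_genes(tables, 4, seed=3, fpkm_col="fpkm_vehicle")
        b = rp.select_control_genes(tables, 4, seed=3, fpkm_col="fpkm_vehicle")
        assert a == b

    def test_differential_gene_never_selected(self):
        tables = self.eligible_tables()
        tables["b"].loc[0, "q_value"] = 0.01  # ok0 significant in one arm
        for seed in range(50):
            chosen = rp.select_control_genes(tables, 4, seed=seed, fpkm_col="fpkm_vehicle")
            assert "ok0" not in chosen
            assert not any(g.startswith("bad") for g in chosen)

    def test_selection_is_uniform_over_seeds(self):
        tables = self.eligible_tables()
        counts = {f"ok{i}": 0 for i in range(12)}
        n, trials = 4, 1000
        for seed in range(trials):
            for g in rp.select_control_genes(tables, n, seed=seed, fpkm_col="fpkm_vehicle"):
                counts[g] += 1
        expected = trials * n / 12
        sigma = np.sqrt(trials * (n / 12) * (1 - n / 12))
        for g, c in counts.items():
            assert abs(c - expected) < 5 * sigma, f"{g}: {c} vs {expected}"

    def test_small_pool_error_reports_size(self):
        tables = self.eligible_tables(n_eligible=3)
        with pytest.raises(ValueError, match="3"):
            rp.select_control_genes(tables, 10, seed=0, fpkm_col="fpkm_vehicle")


class TestClassifyAffected:
    def ranked(self, rows):
        table = make_table(rows)
        return rp.call_responsive_genes(table, "vehicle", "egf"), table

    def test_top_tier_reduction_rule(self):
        # one responsive gene => it is the top 30% tier
        calls, ctrl = self.ranked([("g", 1.0, 10.0, 10.0, 0.001)])
        pert_affected = make_table([("g", 1.0, 4.0, 4.0, 0.001)])
        pert_untouched = make_table([("g", 1.0, 6.0, 6.0, 0.001)])
        hit = rp.classify_affected(calls, ctrl, pert_affected, "vehicle", "egf")
        miss = rp.classify_affected(calls, ctrl, pert_untouched, "vehicle", "egf")
        assert hit.loc[0, "affected"] and hit.loc[0, "rule"] == "top-tier-reduction"
        assert not miss.loc[0, "affected"]

    def test_lower_tier_uses_lost_significance(self):
        rows = [(f"g{i}", 1.0, 20.0 - i, 20.0 - i, 0.001) for i in range(4)]
        calls, ctrl = self.ranked(rows)
        # g3 is rank 4 (below ceil(0.3*4)=2): affected iff q>0.05 and fold<2
        pert = make_table(
            [("g0", 1.0, 20.0, 20.0, 0.001), ("g1", 1.0, 19.0, 19.0, 0.001),
             ("g2", 1.0, 18.0, 18.0, 0.001), ("g3", 1.0, 1.0, 1.0, 0.9)]
        )
        out = rp.classify_affected(calls, ctrl, pert, "vehicle", "egf")
        tagged = dict(zip(out["feature_id"], out["rule"]))
        assert tagged["g3"] == "lost-significance"
        assert all(tagged[f"g{i}"] == "" for i in range(3))

    def test_unranked_input_rejected(self):
        table = make_table([("g", 1.0, 10.0, 10.0, 0.001)])
        with pytest.raises(ValueError, match="rank"):
            rp.classify_affected(table, table, table, "vehicle", "egf")

    def test_reduction_factor_one_marks_everything(self):
        rows = [(f"g{i}", 1.0, 10.0 + i, 10.0 + i, 0.001) for i in range(10)]
        calls, ctrl = self.ranked(rows)
        out = rp.classify_affected(
            calls, ctrl, ctrl, "vehicle", "egf",
            reduction_factor=1.0, tier2_min_q=-1.0, tier2_max_fold=float("inf"),
        )
        assert out["affected"].all()

    def test_identity_perturbation_with_zero_factor_marks_none(self):
        rows = [(f"g{i}", 1.0, 10.0 + i, 10.0 + i, 0.001) for i in range(10)]
        calls, ctrl = self.ranked(rows)
        out = rp.classify_affected(calls, ctrl, ctrl, "vehicle", "egf", reduction_factor=0.0)
        assert not out["affected"].any()

    def test_recovers_planted_suppressed_subset_noise_free(self):
        cfg = simulate.CohortConfig(
            seed=13, noise_sd=0.0,
            perturbations={"shints11": simulate.Perturbation(0.6, 0.0)},
        )
        ctrl = simulate.simulate_expression(cfg, "egf", features="genes")
        pert = simulate.simulate_expression(cfg, "shints11", features="genes")
        responsive, _, affected = simulate._expression_truth(cfg)
        calls = rp.call_responsive_genes(ctrl, "vehicle", "egf")
        out = rp.classify_affected(
            calls, ctrl, pert, "vehicle", "egf", perturbed_after="shints11"
        )
        called = set(out.loc[out["affected"], "feature_id"])
        assert called == affected["shints11"] & responsive


class TestReductionRule:
    def test_boundary_is_inclusive(self):
        ctrl = make_table([("g", 5.0, 10.0, 2.0, 0.01)])
        down = make_table([("g", 5.0, 6.0, 1.2, 0.2)])
        close = make_table([("g", 5.0, 6.5, 1.3, 0.2)])
        assert rp.classify_affected_reduction(ctrl, down, "fpkm_egf") == {"g"}
        assert rp.classify_affected_reduction(ctrl, close, "fpkm_egf") == set()
        assert rp.classify_affected_reduction(ctrl, down, "fpkm_egf", inclusive=False) == set()

    def test_matches_elementwise_oracle_on_random_tables(self):
        rng = np.random.default_rng(88)
        for _ in range(50):
            feats = [f"g{i}" for i in range(15)]
            ctrl = make_table([(f, 1.0, float(rng.uniform(1, 20)), 1.0, 0.5) for f in feats])
            pert = make_table([(f, 1.0, float(rng.uniform(0, 20)), 1.0, 0.5) for f in feats])
            expected = {
                f for f in feats
                if pert.set_index("feature_id").at[f, "fpkm_egf"]
                <= 0.6 * ctrl.set_index("feature_id").at[f, "fpkm_egf"]
            }
            assert rp.classify_affected_reduction(ctrl, pert, "fpkm_egf") == expected
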