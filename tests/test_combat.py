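"""ComBat family: L/S estimation, EB shrinkage, cascades, order selection."""

import numpy as np
import pandas as pd
import pytest

from cloudharmony import (
    HarmonizationPlan,
    LesionTable,
    SimulationConfig,
    combat_apply,
    combat_fit,
    generate_cohort,
    opnested_select_order,
    sequential_harmonize,
    standardize,
)
from cloudharmony.combat import CombatApplyError, CombatFitError

from _oracles import bf_ls_correct


def ls_table(gamma, delta, n_per_batch=100, d=5, seed=0, intercept=0.0):
    """Table drawn exactly from the L/S model: Y = a + gamma_i + delta_i*eps."""
    rng = np.random.default_rng(seed)
    rows = []
    for bi, (g, dl) in enumerate(zip(gamma, delta)):
        y = intercept + g + dl * rng.standard_normal((n_per_batch, d))
        for j in range(n_per_batch):
            rows.append(
                [f"L{bi}_{j}", f"P{bi}_{j}", f"C{bi + 1}", f"S{bi + 1}", *y[j]]
            )
    cols = ["lesion_id", "patient_id", "center", "scanner"] + [f"f{i}" for i in range(1, d + 1)]
    return LesionTable(pd.DataFrame(rows, columns=cols))


class TestCombatFitApply:
    def test_single_batch_correction_is_identity(self):
        table = ls_table([0.5], [1.3], n_per_batch=40, seed=1)
        model = combat_fit(table, "center", mode="ls-only")
        out = combat_apply(model, table)
        assert np.max(np.abs(out.features - table.features)) < 1e-8

    def test_parameter_recovery_on_ls_simulation(self):
        table = ls_table([-1.0, 1.0], [0.5, 2.0], n_per_batch=500, d=45, seed=7)
        model = combat_fit(table, "center")
        add = model.additive_effects()
        mult = model.multiplicative_effects()
        assert np.mean(np.abs(add["C1"] - (-1.0))) < 0.1
        assert np.mean(np.abs(add["C2"] - 1.0)) < 0.1
        assert np.mean(np.abs(mult["C1"] / 0.5 - 1.0)) < 0.1
        assert np.mean(np.abs(mult["C2"] / 2.0 - 1.0)) < 0.1

    def test_correction_matches_batch_moments(self):
        table = ls_table([-1.0, 1.0], [0.5, 2.0], n_per_batch=500, d=45, seed=8)
        model = combat_fit(table, "center")
        out = combat_apply(model, table)
        x = out.features
        lab = out.df["center"].to_numpy()
        pooled_sd = x.std(axis=0)
        mean_gap = np.abs(x[lab == "C1"].mean(0) - x[lab == "C2"].mean(0)) / pooled_sd
        var_ratio = x[lab == "C1"].var(0) / x[lab == "C2"].var(0)
        assert np.all(mean_gap < 0.05 * 5)  # per-feature, well inside the pooled band
        assert mean_gap.mean() < 0.05
        assert np.all((var_ratio > 0.8) & (var_ratio < 1.25))
        assert np.median(var_ratio) == pytest.approx(1.0, abs=0.1)

    def test_eb_shrinks_more_than_ls(self):
        # across many tiny two-batch tables, EB estimates of gamma vary less
        # across features than the raw per-batch moments
        sds_eb, sds_ls = [], []
        for seed in range(100):
            table = ls_table([-0.5, 0.5], [1.0, 1.0], n_per_batch=10, d=8, seed=seed)
            eb = combat_fit(table, "center", mode="eb-parametric")
            ls = combat_fit(table, "center", mode="ls-only")
            sds_eb.append(eb.gamma_star.std(axis=1).mean())
            sds_ls.append(ls.gamma_star.std(axis=1).mean())
        assert np.mean(sds_eb) < np.mean(sds_ls)

    def test_identity_when_parameters_are_null(self):
        table = ls_table([0.3, -0.3], [1.1, 0.9], n_per_batch=30, seed=3)
        model = combat_fit(table, "center", mode="ls-only")
        model.gamma_star[:] = 0.0
        model.delta_star[:] = 1.0
        out = combat_apply(model, table)
        assert np.max(np.abs(out.features - table.features)) < 1e-10

    def test_refit_on_corrected_data_finds_nothing(self):
        table = ls_table([-1.0, 1.0], [0.5, 2.0], n_per_batch=200, d=10, seed=4)
        corrected = combat_apply(combat_fit(table, "center", mode="ls-only"), table)
        refit = combat_fit(corrected, "center", mode="ls-only")
        assert np.max(np.abs(refit.gamma_star)) < 1e-6
        assert np.max(np.abs(refit.delta_star - 1.0)) < 1e-6
        again = combat_apply(refit, corrected)
        assert np.max(np.abs(again.features - corrected.features)) < 1e-6

    def test_ls_only_equalizes_batch_means_exactly(self):
        table = ls_table([-2.0, 2.0], [1.0, 3.0], n_per_batch=50, d=4, seed=5)
        out = combat_apply(combat_fit(table, "center", mode="ls-only"), table)
        x = out.features
        lab = out.df["center"].to_numpy()
        gap = x[lab == "C1"].mean(0) - x[lab == "C2"].mean(0)
        assert np.max(np.abs(gap)) < 1e-8

    def test_brute_force_oracle_equivalence(self):
        for seed in range(5):
            table = ls_table([-0.7, 0.4, 1.0], [0.6, 1.0, 1.8], n_per_batch=20, d=5, seed=seed)
            out = combat_apply(combat_fit(table, "center", mode="ls-only"), table)
            oracle = bf_ls_correct(table.features, list(table.df["center"]))
            assert np.max(np.abs(out.features - oracle)) < 1e-10

    def test_recombat_converges_to_combat_as_ridge_vanishes(self):
        table = ls_table([-1.0, 1.0], [0.8, 1.2], n_per_batch=100, d=6, seed=6)
        plain = combat_fit(table, "center")
        tiny = combat_fit(table, "center", ridge=1e-10)
        assert np.max(np.abs(plain.gamma_star - tiny.gamma_star)) < 1e-6
        assert np.max(np.abs(plain.delta_star - tiny.delta_star)) < 1e-6

    def test_errors(self):
        table = ls_table([0.0, 1.0], [1.0, 1.0], n_per_batch=10, seed=9)
        df = table.df.drop(index=range(1, 10)).reset_index(drop=True)  # batch C1 -> 1 sample
        with pytest.raises(CombatFitError, match="fewer than 2"):
            combat_fit(LesionTable(df), "center")
        model = combat_fit(table, "center")
        other = ls_table([0.0], [1.0], n_per_batch=5, seed=10)
        other.df["center"] = "C9"
        with pytest.raises(CombatApplyError, match="not seen"):
            combat_apply(model, LesionTable(other.df))

    def test_ids_never_altered(self):
        table = ls_table([-1.0, 1.0], [0.5, 2.0], n_per_batch=30, seed=11)
        out = combat_apply(combat_fit(table, "center"), table)
        for col in ("lesion_id", "patient_id", "center", "scanner"):
            assert (out.df[col] == table.df[col]).all()


class TestCascades:
    def test_single_factor_plan_equals_fit_apply(self):
        table = ls_table([-1.0, 1.0], [0.7, 1.4], n_per_batch=80, seed=12)
        direct = combat_apply(combat_fit(table, "center"), table)
        cascaded, models = sequential_harmonize(table, HarmonizationPlan(["center"]))
        assert len(models) == 1
        assert np.max(np.abs(direct.features - cascaded.features)) < 1e-12

    def test_additive_only_cohort_both_orders_deconfound(self):
        cfg = SimulationConfig(
            seed=20,
            center_scale_log_sd=0.0,
            scanner_scale_log_sd=0.0,
            interaction_strength=0.0,
            nonlinear_strength=0.0,
        )
        _, confounded, _, _ = generate_cohort(cfg)
        std, _ = standardize(confounded)
        from cloudharmony.evaluation import confounder_accuracy

        labels = std.df["center"].to_numpy()
        prevalence = max(np.mean(labels == c) for c in set(labels))
        for order in (["center", "scanner"], ["scanner", "center"]):
            corrected, _ = sequential_harmonize(std, HarmonizationPlan(order))
            acc = confounder_accuracy(corrected.features, labels, n_trials=10, seed=0)
            assert abs(acc.mean - prevalence) < 0.08

    def test_interaction_makes_orders_disagree(self):
        cfg = SimulationConfig(
            seed=21, n_patients_per_center=(40, 30), interaction_strength=1.0
        )
        _, confounded, _, _ = generate_cohort(cfg)
        std, _ = standardize(confounded)
        a, _ = sequential_harmonize(std, HarmonizationPlan(["center", "scanner"]))
        b, _ = sequential_harmonize(std, HarmonizationPlan(["scanner", "center"]))
        assert np.max(np.abs(a.features - b.features)) > 0.01


class TestOpnested:
    def test_tie_break_is_lexicographic(self):
        # symmetric additive-only effects: both orders leave ~the same counts;
        # the selector must deterministically return the first enumeration
        cfg = SimulationConfig(
            seed=22,
            n_patients_per_center=(30, 30),
            center_effect_sd=0.0,
            scanner_effect_sd=0.0,
            center_scale_log_sd=0.0,
            scanner_scale_log_sd=0.0,
            interaction_strength=0.0,
            nonlinear_strength=0.0,
        )
        _, confounded, _, _ = generate_cohort(cfg)
        std, _ = standardize(confounded)
        order, _, report = opnested_select_order(std, ["scanner", "center"])
        counts = {k: v["total"] for k, v in report.items()}
        assert counts["center-scanner"] == counts["scanner-center"]
        assert order == ("center", "scanner")  # first in lexicographic enumeration

    def test_report_counts_bounded(self):
        cfg = SimulationConfig(seed=23, n_patients_per_center=(30, 25))
        _, confounded, _, _ = generate_cohort(cfg)
        std, _ = standardize(confounded)
        _, _, report = opnested_select_order(std, ["center", "scanner"])
        for entry in report.values():
            for count in entry["per_factor"].values():
                assert 0 <= count <= std.d
            assert entry["total"] <= std.d * 2

    def test_correction_removes_residual_associations(self):
        # before correction many features associate with both factors; the
        # selected cascade must drive the counts down (to zero here, since a
        # full two-factor cascade equalizes every batch's location)
        from cloudharmony.combat import _association_count

        cfg = SimulationConfig(seed=31, n_patients_per_center=(35, 30))
        _, confounded, _, _ = generate_cohort(cfg)
        std, _ = standardize(confounded)
        before = _association_count(std, ["center", "scanner"], 0.05)
        assert before["center"] > std.d // 2 and before["scanner"] > std.d // 2
        order, corrected, report = opnested_select_order(std, ["center", "scanner"])
        chosen = report["-".join(order)]
        assert chosen["total"] == min(e["total"] for e in report.values())
        after = _association_count(corrected, ["center", "scanner"], 0.05)
        assert after["center"] + after["scanner"] < (before["center"] + before["scanner"]) // 4

    def test_requires_two_factors(self, small_table):
        with pytest.raises(ValueError):
            opnested_select_order(small_table, ["center"])
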