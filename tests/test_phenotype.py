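"""RBG virulence, host-range grading, one-step fits, ANOVA/contrasts."""

import numpy as np
import pandas as pd
import pytest

from oracles import two_way_anova_oracle
from rhizophage.io import AssayTable
from rhizophage.phenotype import (
    anova_with_contrasts,
    compute_rbg,
    fit_one_step,
    grade_host_range,
)
from rhizophage.simulate import sim_one_step


def od_table(plus_vals, minus_vals, times=(0.0, 600.0)):
    rows = []
    for treat, vals in (("phage+", plus_vals), ("phage-", minus_vals)):
        for t, v in zip(times, vals):
            rows.append((f"s_{treat}", "p1", "h1", 1, t, v, treat))
    return AssayTable(pd.DataFrame(rows, columns=[
        "series_id", "phage_id", "host_id", "replicate", "time", "value",
        "treatment",
    ]))


class TestRBG:
    def test_arithmetic(self):
        table = od_table((0.1, 0.3), (0.1, 0.6))  # gains 0.2 vs 0.5
        assert compute_rbg(table, tx=600)[0].rbg == pytest.approx(0.6)

    def test_equal_growth_gives_zero(self):
        table = od_table((0.1, 0.5), (0.1, 0.5))
        assert compute_rbg(table, tx=600)[0].rbg == pytest.approx(0.0)

    def test_flat_phage_series_gives_one(self):
        table = od_table((0.1, 0.1), (0.1, 0.6))
        assert compute_rbg(table, tx=600)[0].rbg == pytest.approx(1.0)

    @pytest.mark.parametrize("offset,scale", [(0.05, 1.0), (0.0, 3.0), (0.02, 2.5)])
    def test_blank_and_gain_invariance(self, offset, scale):
        """RBG is unchanged by blank subtraction (adding a constant) and
        by instrument gain (multiplying all ODs)."""
        base = od_table((0.10, 0.25), (0.10, 0.60))
        ref = compute_rbg(base, tx=600)[0].rbg
        transformed = AssayTable(
            base.df.assign(value=base.df["value"] * scale + offset)
        )
        assert compute_rbg(transformed, tx=600)[0].rbg == pytest.approx(ref)

    def test_nonpositive_control_gain_flagged(self):
        table = od_table((0.1, 0.3), (0.5, 0.4))
        res = compute_rbg(table, tx=600)[0]
        assert np.isnan(res.rbg) and res.flag == "control-gain-nonpositive"

    def test_missing_control_rejected(self):
        df = od_table((0.1, 0.3), (0.1, 0.5)).df
        with pytest.raises(ValueError, match="control"):
            compute_rbg(AssayTable(df[df.treatment == "phage+"]), tx=600)


class TestHostRangeGrading:
    @pytest.mark.parametrize(
        "clearing,plaques,regrowth,pcr,grade,flag",
        [
            ("none", False, False, None, "none", None),
            ("turbid", False, False, None, "weak", None),
            ("turbid", True, False, None, "weak", None),
            ("clear", False, False, None, "weak", None),
            ("clear", True, False, None, "strong", None),
            ("clear", True, True, True, "lysogenization", None),
            ("clear", True, True, False, "strong", None),
            ("clear", True, True, None, "strong", "lysogeny-untested"),
        ],
    )
    def test_grading_rules(self, clearing, plaques, regrowth, pcr, grade, flag):
        call = grade_host_range("p", "h", clearing, plaques, regrowth, pcr)
        assert (call.grade, call.flag) == (grade, flag)

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            grade_host_range("p", "h", "hazy")


class TestOneStepFit:
    def test_noise_free_recovery(self):
        table = sim_one_step(latent_min=50, burst_size=255, noise_sd=0.0, seed=0)
        fit = fit_one_step(table)[0]
        assert abs(fit.latent_min - 50) <= 30  # one sampling step
        assert fit.burst_size == pytest.approx(255, rel=0.01)

    def test_flat_series_flagged(self):
        table = sim_one_step(burst_size=1.0, noise_sd=0.0, seed=0)
        fit = fit_one_step(table)[0]
        assert fit.latent_min is None and fit.flag == "no-rise"
        assert fit.burst_size == pytest.approx(1.0, abs=0.05)

    def test_noisy_replicates_near_truth(self):
        """Four replicates at a long latent period (90 min) and moderate
        burst (60): the mean fitted latent period stays within 5 min."""
        table = sim_one_step(
            latent_min=90, burst_size=60, noise_sd=0.05, n_rep=4, seed=1
        )
        fits = fit_one_step(table)
        assert len(fits) == 4
        assert np.mean([f.latent_min for f in fits]) == pytest.approx(90, abs=5)
        assert np.mean([f.burst_size for f in fits]) == pytest.approx(60, rel=0.1)

    def test_recovery_across_parameter_grid(self):
        """Across latent periods 30-120 min and bursts 10-300, median
        latent error stays within half a step and burst within 10%."""
        lat_errs, burst_rel_errs = [], []
        seed = 0
        for latent in (30, 60, 90, 120):
            for burst in (10, 60, 150, 300):
                for _ in range(3):
                    seed += 1
                    table = sim_one_step(
                        latent_min=latent, burst_size=burst,
                        noise_sd=0.05, seed=seed,
                    )
                    fit = fit_one_step(table)[0]
                    lat_errs.append(abs(fit.latent_min - latent))
                    burst_rel_errs.append(abs(fit.burst_size - burst) / burst)
        assert np.median(lat_errs) <= 15  # half the 30-min sampling step
        assert np.median(burst_rel_errs) <= 0.10

    def test_too_few_points_rejected(self):
        table = sim_one_step(horizon_min=120, step_min=30, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError, match="6 time points"):
            fit_one_step(table)


class TestAnova:
    def _design(self, n_rep=3):
        a = np.repeat(["vA", "vB", "vC"], 2 * n_rep)
        b = np.tile(np.repeat(["h1", "h2"], n_rep), 3)
        return a, b

    def test_all_equal_values_null(self):
        a, b = self._design()
        rep = anova_with_contrasts(np.ones(18), a, b)
        ft = rep.factor_table.set_index("term")
        for term in ("C(A)", "C(B)", "C(A):C(B)"):
            assert ft.loc[term, "F"] == 0.0 and ft.loc[term, "p"] == 1.0
        assert (rep.contrast_table["p"] == 1.0).all()

    def test_matches_closed_form_two_way(self):
        rng = np.random.default_rng(3)
        a, b = self._design()
        values = rng.normal(size=18) + (a == "vC") * 1.5
        rep = anova_with_contrasts(values, a, b)
        oracle = two_way_anova_oracle(values, a, b)
        ft = rep.factor_table.set_index("term")
        for term, key in [("C(A)", "A"), ("C(B)", "B"), ("C(A):C(B)", "A:B")]:
            assert ft.loc[term, "F"] == pytest.approx(oracle[key][0], abs=1e-9)

    def test_df_structure_of_3x2x3_design(self):
        """Three phages x two hosts x three replicates gives the (2, 12)
        phage-term degrees of freedom of the standard virulence design."""
        rng = np.random.default_rng(4)
        a, b = self._design()
        rep = anova_with_contrasts(rng.normal(size=18), a, b)
        ft = rep.factor_table.set_index("term")
        assert ft.loc["C(A)", "df"] == 2
        assert rep.residual_df == 12
        assert ft["df"].sum() == 17  # n - 1

    def test_contrast_count_and_sign(self):
        a, b = self._design()
        values = (a == "vC") * 2.0 + 0.001 * np.arange(18)
        rep = anova_with_contrasts(values, a, b)
        assert len(rep.contrast_table) == 3
        vc_vs_va = rep.contrast_table.set_index("pair").loc["vC-vA"]
        assert vc_vs_va["t"] > 0

    def test_empty_cell_named_in_error(self):
        a = ["x", "x", "y", "y"]
        b = ["h1", "h1", "h1", "h2"]
        with pytest.raises(ValueError, match="'x'.*'h2'"):
            anova_with_contrasts([1.0, 2.0, 3.0, 4.0], a, b)

    def test_one_way_without_factor_b(self):
        rng = np.random.default_rng(5)
        a = np.repeat(["x", "y", "z"], 4)
        rep = anova_with_contrasts(rng.normal(size=12), a)
        ft = rep.factor_table.set_index("term")
        assert ft.loc["C(A)", "df"] == 2 and rep.residual_df == 9

    def test_tukey_adjusts_upward(self):
        rng = np.random.default_rng(6)
        a, b = self._design()
        values = rng.normal(size=18) + (a == "vC")
        plain = anova_with_contrasts(values, a, b)
        adj = anova_with_contrasts(values, a, b, tukey=True)
        merged = plain.contrast_table.merge(
            adj.contrast_table, on="pair", suffixes=("_plain", "_tukey")
        )
        assert (merged["p_tukey"] >= merged["p_plain"] - 1e-9).all()
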