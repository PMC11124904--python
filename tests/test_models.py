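import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from circumkin.models import (
    CrossIndexGAM,
    KinematicsLMM,
    ModelSpec,
    SwitchCountGLMM,
    bspline_curve,
    fit_lmm,
    pairwise_contrasts,
    type3_wald,
)
from circumkin.simulate import simulate_cohort


@pytest.fixture(scope="module")
def null_cohort():
    table, truth = simulate_cohort(seed=7)
    return table, truth


class TestKinematicsLMM:
    def test_row_permutation_invariance(self, null_cohort):
        table, _ = null_cohort
        r1 = KinematicsLMM(table, "mean_speed_mm_min").fit()
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        r2 = KinematicsLMM(shuffled, "mean_speed_mm_min").fit()
        pd.testing.assert_series_equal(r1.params, r2.params, rtol=1e-6)

    def test_null_coefficients_near_zero(self):
        """Under a no-effect generator the fixed coefficients must sit
        within 3 SE of zero in at least 95% of seeded replicates."""
        hits = total = 0
        for seed in range(60):
            table, _ = simulate_cohort(seed=30_000 + seed)
            res = KinematicsLMM(
                table, "mean_speed_mm_min", random_slope=None
            ).fit()
            for name in ("condition[NoSupport]", "condition[NoSupport]:phase[POST]"):
                total += 1
                if abs(res.params[name]) < 3 * res.bse[name]:
                    hits += 1
        assert hits / total >= 0.95

    def test_interaction_sign_recovered(self):
        eff = {"index": {("mean_speed_mm_min", "Support", "POST"): 2.0}}
        table, truth = simulate_cohort(effects=eff, seed=11)
        res = KinematicsLMM(table, "mean_speed_mm_min").fit()
        cm = truth["cells"]["index_means"]
        k = "mean_speed_mm_min"
        expected = (
            cm[(k, "NoSupport", "POST")]
            - cm[(k, "NoSupport", "PRE")]
            - cm[(k, "Support", "POST")]
            + cm[(k, "Support", "PRE")]
        ) / 4.0
        coef = res.params["condition[NoSupport]:phase[POST]"]
        assert np.sign(coef) == np.sign(expected)
        assert res.type3("condition:phase").p_value < 0.05

    def test_singular_random_slope_is_flagged_not_fatal(self, null_cohort):
        table, _ = null_cohort
        res = KinematicsLMM(table, "mean_speed_mm_min", random_slope="condition").fit()
        assert res.singular  # condition is between-plant: slope unidentified
        assert np.all(np.isfinite(res.bse))

    def test_fit_lmm_spec_surface(self, null_cohort):
        table, _ = null_cohort
        spec = ModelSpec(
            response="area_mm2",
            fixed=("condition", "phase", "condition:phase"),
            random_slope=None,
        )
        res = fit_lmm(table, spec)
        assert res.nobs == len(table)
        assert set(res.type3_table()["term"]) == set(spec.fixed)


class TestTypeIII:
    def test_single_coefficient_wald_identity(self, null_cohort):
        table, _ = null_cohort
        res = KinematicsLMM(table, "mean_speed_mm_min", random_slope=None).fit()
        t = type3_wald(res, "phase")
        z = res.params["phase[POST]"] / res.bse["phase[POST]"]
        np.testing.assert_allclose(t.chi_square, z**2, rtol=1e-10)
        assert t.df == 1

    def test_absent_term_errors(self, null_cohort):
        table, _ = null_cohort
        res = KinematicsLMM(table, "mean_speed_mm_min", random_slope=None).fit()
        with pytest.raises(KeyError):
            res.type3("landmark")

    def test_two_level_wald_z_is_sqrt_chi2(self, null_cohort):
        table, _ = null_cohort
        res = KinematicsLMM(table, "mean_speed_mm_min", random_slope=None).fit()
        contrasts = pairwise_contrasts(res, ["phase"])
        assert len(contrasts) == 1
        chi2 = res.type3("phase").chi_square
        np.testing.assert_allclose(abs(contrasts[0].z), np.sqrt(chi2), rtol=1e-8)


class TestContrasts:
    def test_four_cells_give_six_contrasts(self, null_cohort):
        table, _ = null_cohort
        res = KinematicsLMM(table, "mean_speed_mm_min", random_slope=None).fit()
        assert len(res.contrasts(["condition", "phase"])) == 6

    def test_ordered_cell_means_reproduced(self):
        eff = {"index": {("area_mm2", "Support", "POST"): 1.6,
                         ("area_mm2", "NoSupport", "POST"): 1.3}}
        table, _ = simulate_cohort(effects=eff, seed=13, sd_obs=0.1, sd_plant=0.05)
        res = KinematicsLMM(table, "area_mm2", random_slope=None).fit()
        em = res.emmeans(["condition", "phase"]).set_index(["condition", "phase"])
        assert (
            em.loc[("Support", "POST"), "emmean"]
            > em.loc[("NoSupport", "POST"), "emmean"]
            > em.loc[("NoSupport", "PRE"), "emmean"]
        )

    def test_tukey_two_means_matches_two_sided_normal(self, null_cohort):
        from circumkin.models import _tukey_p

        z = 1.7
        np.testing.assert_allclose(_tukey_p(z, 2), 2 * scipy.stats.norm.sf(z), rtol=1e-3)


class TestCrossIndexGAM:
    def test_linear_relation_has_edf_near_one(self):
        edfs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 600
            plant = np.repeat([f"P{i:02d}" for i in range(24)], n // 24)
            x = rng.normal(size=n)
            y = 0.8 * x + rng.normal(0, 0.2, n)
            res = CrossIndexGAM(
                pd.DataFrame({"plant_id": plant, "x": x, "y": y}), "y", "x", controls=()
            ).fit()
            edfs.append(res.edf)
        assert abs(np.median(edfs) - 1.0) <= 0.3

    def test_three_cycle_sinusoid_has_edf_above_three(self):
        rng = np.random.default_rng(1)
        n = 600
        plant = np.repeat([f"P{i:02d}" for i in range(24)], n // 24)
        x = rng.uniform(-2, 2, size=n)
        y = np.sin(2 * np.pi * 3 * (x + 2) / 4) + rng.normal(0, 0.3, n)
        res = CrossIndexGAM(
            pd.DataFrame({"plant_id": plant, "x": x, "y": y}), "y", "x", controls=()
        ).fit()
        assert res.edf > 3.0
        assert res.p_value < 1e-6

    def test_null_p_values_roughly_uniform(self):
        ps = []
        for seed in range(120):
            rng = np.random.default_rng(40_000 + seed)
            plant = np.repeat([f"P{i:02d}" for i in range(24)], 10)
            df = pd.DataFrame(
                {"plant_id": plant, "x": rng.normal(size=240), "y": rng.normal(size=240)}
            )
            ps.append(CrossIndexGAM(df, "y", "x", controls=()).fit().p_value)
        assert scipy.stats.kstest(np.array(ps), "uniform").pvalue > 0.01

    def test_few_unique_predictor_values_reduce_basis(self):
        rng = np.random.default_rng(2)
        plant = np.repeat(["A", "B"], 30)
        x = np.tile(np.arange(6.0), 10)
        y = x + rng.normal(0, 0.1, 60)
        with pytest.warns(UserWarning, match="unique predictor"):
            res = CrossIndexGAM(
                pd.DataFrame({"plant_id": plant, "x": x, "y": y}), "y", "x", controls=()
            ).fit()
        assert np.isfinite(res.edf)


class TestSwitchCountGLMM:
    @staticmethod
    def _count_table(rate_map, seed, n_plants=24, n_leaves=3):
        rng = np.random.default_rng(seed)
        rows = []
        ranks = ["Third last", "Second last", "Last"]
        for p in range(n_plants):
            cond = "Support" if p < 16 else "NoSupport"
            u = rng.normal(0, 0.2)
            for rank in ranks:
                mu = rate_map.get(rank, 3.0) * np.exp(u)
                rows.append(
                    {
                        "plant_id": f"P{p:02d}",
                        "condition": cond,
                        "leaf_rank": rank,
                        "n": int(rng.poisson(mu)),
                    }
                )
        return pd.DataFrame(rows)

    def test_null_coefficients_within_three_se(self):
        table = self._count_table({}, seed=0)
        res = SwitchCountGLMM(table, "n", ["condition", "leaf_rank"]).fit()
        for name in res.params.index:
            if name == "Intercept":
                continue
            assert abs(res.params[name]) < 3 * res.bse[name]

    def test_rate_ratio_two_recovered(self):
        table = self._count_table({"Last": 6.0, "Third last": 3.0}, seed=1)
        res = SwitchCountGLMM(table, "n", ["condition", "leaf_rank"]).fit()
        grid, L = res.design.emm_rows(["leaf_rank"])
        i = grid.index[grid.leaf_rank == "Last"][0]
        j = grid.index[grid.leaf_rank == "Third last"][0]
        l = L[i] - L[j]
        est = float(l @ res.params.to_numpy())
        se = float(np.sqrt(l @ res.cov_params.to_numpy() @ l))
        assert abs(est - np.log(2.0)) < 3 * se

    def test_non_integer_counts_rejected(self):
        table = self._count_table({}, seed=2)
        table.loc[0, "n"] = 1.5
        with pytest.raises(ValueError):
            SwitchCountGLMM(table, "n", ["condition"])

    def test_all_zero_cell_flagged(self):
        table = self._count_table({}, seed=3)
        table.loc[table.leaf_rank == "Last", "n"] = 0
        model = SwitchCountGLMM(table, "n", ["condition", "leaf_rank"])
        assert model.all_zero_cells
        with pytest.warns(UserWarning, match="all-zero"):
            model.fit()


class TestBSplineCurve:
    def test_constant_data_gives_constant_curve(self):
        x = np.linspace(0, 10, 30)
        curve = bspline_curve(x, np.full(30, 4.2))
        np.testing.assert_allclose(curve(np.linspace(0, 10, 7)), 4.2, atol=1e-9)

    def test_linear_data_reproduced_exactly(self):
        x = np.linspace(-3, 5, 40)
        y = 2.0 * x - 1.0
        curve = bspline_curve(x, y)
        np.testing.assert_allclose(curve(x), y, atol=1e-8)

    def test_noisy_quadratic_within_noise_envelope(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 1, 200)
        truth = 3 * (x - 0.4) ** 2
        y = truth + rng.normal(0, 0.05, 200)
        curve = bspline_curve(x, y)
        assert np.max(np.abs(curve(x) - truth)) < 4 * 0.05

    def test_df_must_be_smaller_than_n(self):
        with pytest.raises(ValueError):
            bspline_curve(np.arange(3.0), np.arange(3.0), df=3)


def _rscript(code: str) -> str:
    proc = subprocess.run(
        ["Rscript", "-e", code], capture_output=True, text=True, timeout=300
    )
    if proc.returncode != 0:
        raise RuntimeError(proc.stderr)
    return proc.stdout


class TestAgainstRReference:
    """Cross-checks against the R reference stack on a shared fixture."""

    def test_lmm_matches_lmer(self, tmp_path, null_cohort):
        table, _ = null_cohort
        sub = table[["plant_id", "condition", "phase", "mean_speed_mm_min"]].copy()
        from circumkin.kinematics import standardize

        sub["y"] = standardize(sub["mean_speed_mm_min"])
        csv = tmp_path / "d.csv"
        sub.to_csv(csv, index=False)
        res = KinematicsLMM(sub, "y", random_slope=None, scale_response=False).fit()
        out = _rscript(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                d$condition <- factor(d$condition); d$phase <- factor(d$phase)
                contrasts(d$condition) <- contr.sum(2)
                contrasts(d$phase) <- contr.sum(2)
                m <- lmer(y ~ condition * phase + (1 | plant_id), data=d, REML=TRUE)
                cat(fixef(m), sqrt(diag(vcov(m))), sep="\\n")
                """
            )
        )
        vals = [float(v) for v in out.split()]
        fe_r, se_r = np.array(vals[:4]), np.array(vals[4:])
        np.testing.assert_allclose(res.params.to_numpy(), fe_r, rtol=1e-4, atol=1e-6)
        np.testing.assert_allclose(res.bse.to_numpy(), se_r, rtol=1e-3, atol=1e-6)

    def test_poisson_glmm_matches_glmer(self, tmp_path):
        table = TestSwitchCountGLMM._count_table({"Last": 5.0}, seed=5)
        csv = tmp_path / "c.csv"
        table.to_csv(csv, index=False)
        res = SwitchCountGLMM(table, "n", ["condition", "leaf_rank"]).fit()
        out = _rscript(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                d$condition <- factor(d$condition)
                d$leaf_rank <- factor(d$leaf_rank)
                contrasts(d$condition) <- contr.sum(2)
                contrasts(d$leaf_rank) <- contr.sum(3)
                m <- glmer(n ~ condition + leaf_rank + (1 | plant_id),
                           data=d, family=poisson)
                cat(fixef(m), sep="\\n")
                """
            )
        )
        fe_r = np.array([float(v) for v in out.split()])
        np.testing.assert_allclose(res.params.to_numpy(), fe_r, rtol=5e-3, atol=5e-3)
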