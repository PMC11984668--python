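"""Paired tests, correlation matrices, partial correlations, ICC and
descriptives, checked against independent distribution oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiconcord.concordance import (
    ConcordanceError,
    compute_icc,
    control_probe_pcs,
    describe_cohort,
    icc_from_wide,
    paired_differences,
    partial_correlations,
    pooled_mean_sd,
    stars,
    tissue_correlations,
)


def make_manifest(n_persons, tissues, ages=None, plate="plate1", cohort="adult"):
    rows = []
    for i in range(n_persons):
        for t in tissues:
            rows.append(
                {
                    "sample_id": f"p{i:03d}_{t}",
                    "person_id": f"p{i:03d}",
                    "tissue": t,
                    "age_years": 30.0 if ages is None else ages[i],
                    "sex": "F" if i % 2 == 0 else "M",
                    "cohort": cohort,
                    "plate": plate if isinstance(plate, str) else plate[i],
                    "bisulfite_rate": 0.95,
                }
            )
    return pd.DataFrame(rows)


def make_estimates(manifest, values, clock="toy", transform="identity"):
    """values: mapping sample_id -> estimate; acceleration = estimate - age."""
    ages = manifest.set_index("sample_id")["age_years"]
    rows = []
    for sid, est in values.items():
        accel = np.nan if transform == "rate" else est - float(ages[sid])
        rows.append(
            {
                "sample_id": sid,
                "clock": clock,
                "raw_score": est,
                "estimate": est,
                "transform": transform,
                "acceleration": accel,
            }
        )
    return pd.DataFrame(rows)


class TestPairedDifferences:
    def test_closed_form_t_with_cdf_oracle(self):
        """Differences [1, 1, 2]: mean 4/3, se 1/3, t=4, df=2, p~0.0572."""
        manifest = make_manifest(3, ["buccal", "saliva"])
        vals = {}
        diffs = [1.0, 1.0, 2.0]
        for i, d in enumerate(diffs):
            vals[f"p{i:03d}_saliva"] = 10.0
            vals[f"p{i:03d}_buccal"] = 10.0 + d
        est = make_estimates(manifest, vals)
        cmp_ = paired_differences(est, manifest, "buccal", "saliva", "toy")
        assert cmp_.mean_diff == pytest.approx(4 / 3, abs=1e-4)
        assert cmp_.se == pytest.approx(1 / 3, abs=1e-4)
        assert cmp_.t_stat == pytest.approx(4.0, abs=1e-9)
        assert cmp_.df == 2
        # independent oracles
        assert cmp_.p_two_sided == pytest.approx(
            2 * stats.t.sf(4.0, 2), abs=1e-12
        )
        t_ref, p_ref = stats.ttest_rel(
            [11.0, 11.0, 12.0], [10.0, 10.0, 10.0]
        )
        assert cmp_.t_stat == pytest.approx(t_ref, abs=1e-9)
        assert cmp_.p_two_sided == pytest.approx(p_ref, abs=1e-8)
        assert cmp_.stars == ""

    def test_identical_estimates_flagged_degenerate(self):
        manifest = make_manifest(3, ["buccal", "saliva"])
        vals = {sid: 25.0 for sid in manifest["sample_id"]}
        est = make_estimates(manifest, vals)
        with pytest.warns(UserWarning, match="zero-variance"):
            cmp_ = paired_differences(est, manifest, "buccal", "saliva", "toy")
        assert cmp_.mean_diff == 0.0
        assert cmp_.degenerate

    def test_persons_lacking_one_tissue_excluded(self):
        manifest = make_manifest(4, ["buccal", "saliva"])
        manifest = manifest[manifest["sample_id"] != "p003_saliva"]
        rng = np.random.default_rng(0)
        vals = {sid: float(v) for sid, v in zip(manifest["sample_id"], rng.normal(30, 5, len(manifest)))}
        est = make_estimates(manifest, vals)
        cmp_ = paired_differences(est, manifest, "buccal", "saliva", "toy")
        assert cmp_.n_pairs == 3

    def test_swap_antisymmetry(self):
        manifest = make_manifest(6, ["buccal", "dbs"])
        rng = np.random.default_rng(1)
        vals = {sid: float(v) for sid, v in zip(manifest["sample_id"], rng.normal(30, 5, len(manifest)))}
        est = make_estimates(manifest, vals)
        ab = paired_differences(est, manifest, "buccal", "dbs", "toy")
        ba = paired_differences(est, manifest, "dbs", "buccal", "toy")
        assert ab.mean_diff == pytest.approx(-ba.mean_diff, abs=1e-12)
        assert ab.se == pytest.approx(ba.se, abs=1e-12)
        assert abs(ab.t_stat) == pytest.approx(abs(ba.t_stat), abs=1e-12)
        assert ab.p_two_sided == pytest.approx(ba.p_two_sided, abs=1e-12)

    def test_too_few_pairs_errors(self):
        manifest = make_manifest(1, ["buccal", "saliva"])
        vals = {sid: 20.0 for sid in manifest["sample_id"]}
        est = make_estimates(manifest, vals)
        with pytest.raises(ConcordanceError):
            paired_differences(est, manifest, "buccal", "saliva", "toy")


class TestTissueCorrelations:
    def test_identical_accelerations_give_unit_correlation(self):
        manifest = make_manifest(5, ["buccal", "saliva"])
        rng = np.random.default_rng(2)
        accel = rng.normal(0, 3, 5)
        vals = {}
        for i in range(5):
            vals[f"p{i:03d}_buccal"] = 30.0 + accel[i]
            vals[f"p{i:03d}_saliva"] = 30.0 + accel[i]
        est = make_estimates(manifest, vals)
        mat = tissue_correlations(est, manifest, "toy")
        assert mat.r.loc["buccal", "saliva"] == pytest.approx(1.0)

    def test_negated_accelerations_give_minus_one(self):
        manifest = make_manifest(5, ["buccal", "saliva"])
        rng = np.random.default_rng(3)
        accel = rng.normal(0, 3, 5)
        vals = {}
        for i in range(5):
            vals[f"p{i:03d}_buccal"] = 30.0 + accel[i]
            vals[f"p{i:03d}_saliva"] = 30.0 - accel[i]
        est = make_estimates(manifest, vals)
        mat = tissue_correlations(est, manifest, "toy")
        assert mat.r.loc["buccal", "saliva"] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal_and_pearson_oracle(self):
        manifest = make_manifest(12, ["buccal", "dbs"])
        rng = np.random.default_rng(4)
        vals = {sid: float(v) for sid, v in zip(manifest["sample_id"], rng.normal(30, 5, len(manifest)))}
        est = make_estimates(manifest, vals)
        mat = tissue_correlations(est, manifest, "toy")
        assert mat.r.loc["buccal", "buccal"] == 1.0
        assert mat.r.loc["buccal", "dbs"] == mat.r.loc["dbs", "buccal"]
        a = [vals[f"p{i:03d}_buccal"] for i in range(12)]
        b = [vals[f"p{i:03d}_dbs"] for i in range(12)]
        r_ref, p_ref = stats.pearsonr(a, b)
        assert mat.r.loc["buccal", "dbs"] == pytest.approx(r_ref, abs=1e-12)
        assert mat.p.loc["buccal", "dbs"] == pytest.approx(p_ref, abs=1e-8)

    def test_null_simulation_type_one_error(self):
        """Independent tissues: mean r ~ 0 and ~5% false positives."""
        n, reps = 50, 500
        manifest = make_manifest(n, ["buccal", "dbs"])
        rng = np.random.default_rng(0)
        rs, hits = [], 0
        for _ in range(reps):
            vals = {
                sid: float(v)
                for sid, v in zip(
                    manifest["sample_id"], rng.normal(30, 5, len(manifest))
                )
            }
            est = make_estimates(manifest, vals)
            mat = tissue_correlations(est, manifest, "toy")
            rs.append(mat.r.loc["buccal", "dbs"])
            hits += mat.p.loc["buccal", "dbs"] < 0.05
        assert abs(np.mean(rs)) < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_rate_clock_uses_pace_values(self):
        manifest = make_manifest(5, ["buccal", "saliva"])
        rng = np.random.default_rng(5)
        pace = rng.normal(1.0, 0.1, 5)
        vals = {}
        for i in range(5):
            vals[f"p{i:03d}_buccal"] = pace[i]
            vals[f"p{i:03d}_saliva"] = pace[i]
        est = make_estimates(manifest, vals, transform="rate")
        mat = tissue_correlations(est, manifest, "toy")
        assert mat.r.loc["buccal", "saliva"] == pytest.approx(1.0)


class TestControlProbePCs:
    def _two_batch_controls(self, n_per_batch=12, n_probes=40, shift=0.3, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.3, 0.7, n_probes)
        cols = {}
        labels = {}
        for b in range(2):
            delta = rng.normal(0, shift, n_probes) if b else np.zeros(n_probes)
            for i in range(n_per_batch):
                sid = f"b{b}_s{i}"
                cols[sid] = np.clip(base + delta + rng.normal(0, 0.02, n_probes), 0, 1)
                labels[sid] = b
        return pd.DataFrame(cols), pd.Series(labels)

    def test_pc1_separates_batches(self):
        controls, labels = self._two_batch_controls()
        scores, _ = control_probe_pcs(controls, 1)
        r = np.corrcoef(scores.iloc[:, 0], labels[scores.index])[0, 1]
        assert abs(r) > 0.8

    def test_zero_pcs_is_noop(self):
        controls, _ = self._two_batch_controls()
        scores, evr = control_probe_pcs(controls, 0)
        assert scores.shape == (controls.shape[1], 0)
        assert evr.empty

    def test_reconstruction_from_orthonormal_loadings(self):
        controls, _ = self._two_batch_controls()
        x = controls.to_numpy()
        x = x - x.mean(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(x.T, full_matrices=False)
        np.testing.assert_allclose(vt @ vt.T, np.eye(vt.shape[0]), atol=1e-8)


class TestPartialCorrelations:
    def _setup(self, n=40, seed=0):
        manifest = make_manifest(n, ["buccal", "dbs"])
        rng = np.random.default_rng(seed)
        return manifest, rng

    def test_orthogonal_covariates_leave_r_unchanged(self):
        manifest, rng = self._setup()
        n = 40
        ya = rng.normal(0, 3, n)
        yb = 0.5 * ya + rng.normal(0, 2, n)
        # covariate exactly orthogonalized against [1, ya, yb]
        c = rng.normal(size=n)
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), ya, yb]))
        c = c - q @ (q.T @ c)
        pcs = pd.DataFrame(
            {"ctrlPC1": np.concatenate([c, c])},
            index=[f"p{i:03d}_buccal" for i in range(n)]
            + [f"p{i:03d}_dbs" for i in range(n)],
        )
        vals = {}
        for i in range(n):
            vals[f"p{i:03d}_buccal"] = 30.0 + ya[i]
            vals[f"p{i:03d}_dbs"] = 30.0 + yb[i]
        est = make_estimates(manifest, vals)
        raw = tissue_correlations(est, manifest, "toy")
        partial = partial_correlations(est, manifest, {}, pcs, "toy")
        assert partial.r.loc["buccal", "dbs"] == pytest.approx(
            raw.r.loc["buccal", "dbs"], abs=1e-6
        )

    def test_partial_matches_pingouin(self):
        import pingouin as pg

        manifest, rng = self._setup(seed=7)
        n = 40
        ya, yb = rng.normal(0, 3, n), rng.normal(0, 3, n)
        cov = rng.normal(size=n)
        pcs = pd.DataFrame(
            {"ctrlPC1": np.concatenate([cov, cov])},
            index=[f"p{i:03d}_buccal" for i in range(n)]
            + [f"p{i:03d}_dbs" for i in range(n)],
        )
        vals = {}
        for i in range(n):
            vals[f"p{i:03d}_buccal"] = 30.0 + ya[i]
            vals[f"p{i:03d}_dbs"] = 30.0 + yb[i]
        est = make_estimates(manifest, vals)
        partial = partial_correlations(est, manifest, {}, pcs, "toy")
        ref = pg.partial_corr(
            data=pd.DataFrame({"a": ya, "b": yb, "c": cov}),
            x="a",
            y="b",
            covar=["c"],
        )
        assert partial.r.loc["buccal", "dbs"] == pytest.approx(
            float(ref["r"].iloc[0]), abs=1e-8
        )
        assert partial.p.loc["buccal", "dbs"] == pytest.approx(
            float(ref["p_val"].iloc[0]), abs=1e-8
        )

    def test_shared_batch_confounding_removed(self):
        """Acceleration correlated only through a shared batch factor:
        raw r is inflated, partial r falls inside the 95% null band."""
        n = 50
        manifest = make_manifest(n, ["buccal", "dbs"])
        rng = np.random.default_rng(11)
        batch = rng.choice([0.0, 1.0], n)
        ya = 4.0 * batch + rng.normal(0, 1, n)
        yb = 4.0 * batch + rng.normal(0, 1, n)
        pc1 = np.concatenate([batch, batch]) + rng.normal(0, 0.01, 2 * n)
        pcs = pd.DataFrame(
            {"ctrlPC1": pc1},
            index=[f"p{i:03d}_buccal" for i in range(n)]
            + [f"p{i:03d}_dbs" for i in range(n)],
        )
        vals = {}
        for i in range(n):
            vals[f"p{i:03d}_buccal"] = 30.0 + ya[i]
            vals[f"p{i:03d}_dbs"] = 30.0 + yb[i]
        est = make_estimates(manifest, vals)
        raw = tissue_correlations(est, manifest, "toy")
        partial = partial_correlations(est, manifest, {}, pcs, "toy")
        assert raw.r.loc["buccal", "dbs"] > 0.5
        assert abs(partial.r.loc["buccal", "dbs"]) < 1.96 / np.sqrt(n - 3)

    def test_perfect_confounding_flagged_degenerate(self):
        n = 20
        manifest = make_manifest(n, ["buccal", "dbs"])
        rng = np.random.default_rng(13)
        c = rng.normal(size=n)
        pcs = pd.DataFrame(
            {"ctrlPC1": np.concatenate([c, c])}, index=[f"p{i:03d}_buccal" for i in range(n)]
            + [f"p{i:03d}_dbs" for i in range(n)]
        )
        vals = {}
        for i in range(n):
            vals[f"p{i:03d}_buccal"] = 30.0 + 2.0 * c[i]
            vals[f"p{i:03d}_dbs"] = 30.0 - 1.0 * c[i]
        est = make_estimates(manifest, vals)
        partial = partial_correlations(est, manifest, {}, pcs, "toy")
        assert np.isnan(partial.r.loc["buccal", "dbs"])
        assert ("buccal", "dbs") in partial.notes


class TestICC:
    def test_two_by_two_anova_oracle(self):
        """[[1,2],[3,4]]: hand-computed MS give the six classical values."""
        wide = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]])
        got = icc_from_wide(wide).set_index("variant")["est"]
        expected = {
            "ICC1": 7 / 9,
            "ICC1k": 0.875,
            "ICC2": 0.8,
            "ICC2k": 8 / 9,
            "ICC3": 1.0,
            "ICC3k": 1.0,
        }
        for variant, val in expected.items():
            assert got[variant] == pytest.approx(val, abs=1e-12)

    def test_identical_profiles_give_unit_single_rater_icc(self):
        rng = np.random.default_rng(14)
        col = rng.normal(0, 5, 10)
        wide = pd.DataFrame({t: col for t in ["a", "b", "c"]})
        got = icc_from_wide(wide).set_index("variant")["est"]
        for v in ("ICC1", "ICC2", "ICC3"):
            assert got[v] == pytest.approx(1.0, abs=1e-9)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(15)
        wide = pd.DataFrame(rng.normal(size=(50, 3)))
        got = icc_from_wide(wide).set_index("variant")["est"]
        band = 1.96 / np.sqrt(50)
        assert abs(got["ICC3"]) < band

    def test_matches_pingouin_estimates_and_bounds(self):
        import pingouin as pg

        rng = np.random.default_rng(16)
        wide = pd.DataFrame(
            rng.normal(size=(15, 4)) + rng.normal(size=(15, 1)) * 2.0
        )
        mine = icc_from_wide(wide).set_index("variant")
        long = (
            wide.rename_axis("person")
            .reset_index()
            .melt(id_vars="person", var_name="rater", value_name="y")
        )
        theirs = pg.intraclass_corr(
            long, targets="person", raters="rater", ratings="y"
        ).set_index("Type")
        pairs = {
            "ICC1": "ICC(1,1)",
            "ICC2": "ICC(A,1)",
            "ICC3": "ICC(C,1)",
            "ICC1k": "ICC(1,k)",
            "ICC2k": "ICC(A,k)",
            "ICC3k": "ICC(C,k)",
        }
        for k, v in pairs.items():
            assert mine.loc[k, "est"] == pytest.approx(
                theirs.loc[v, "ICC"], abs=1e-8
            )
            assert mine.loc[k, "p"] == pytest.approx(
                theirs.loc[v, "pval"], abs=1e-8
            )
            ci = theirs.loc[v, "CI95"]  # pingouin rounds to 2 decimals
            assert mine.loc[k, "ci_lower"] == pytest.approx(ci[0], abs=5e-3)
            assert mine.loc[k, "ci_upper"] == pytest.approx(ci[1], abs=5e-3)

    def test_listwise_deletion_and_estimate_pipeline(self):
        manifest = make_manifest(6, ["buccal", "saliva", "dbs"])
        manifest = manifest[manifest["sample_id"] != "p005_dbs"]
        rng = np.random.default_rng(17)
        vals = {sid: float(v) for sid, v in zip(manifest["sample_id"], rng.normal(30, 5, len(manifest)))}
        est = make_estimates(manifest, vals)
        icc = compute_icc(est, manifest, "toy")
        assert icc.n == 5 and icc.k == 3


class TestDescriptives:
    def test_pooled_stratum_arithmetic(self):
        """Combining the two cohort strata reproduces the pooled line."""
        mean, sd = pooled_mean_sd([36, 47], [11.94, 44.27], [1.23, 16.56])
        # inputs are the printed (2-decimal) stratum statistics, so the
        # recomputed pooled values agree to one unit in the last place
        assert mean == pytest.approx(30.25, abs=0.01)
        assert sd == pytest.approx(20.35, abs=0.01)

    def test_counts_percentages_and_age_summary(self):
        ages_child = [10.0] * 3
        ages_adult = [40.0, 50.0]
        m1 = make_manifest(3, ["buccal"], ages=ages_child, cohort="child")
        m2 = make_manifest(2, ["buccal", "pbmc"], ages=ages_adult, cohort="adult")
        m2["sample_id"] = m2["sample_id"].str.replace("p0", "q0")
        m2["person_id"] = m2["person_id"].str.replace("p0", "q0")
        manifest = pd.concat([m1, m2], ignore_index=True)
        table = describe_cohort(manifest)
        assert table.loc["n", "total"] == 5
        assert table.loc["age_mean", "total"] == pytest.approx(24.0)
        assert table.loc["sex_F_pct", "child"] == pytest.approx(66.7)
        assert table.loc["tissue_pbmc_pct", "adult"] == pytest.approx(100.0)
        assert table.loc["tissue_pbmc_n", "total"] == 2

    def test_single_person_sd_missing(self):
        manifest = make_manifest(1, ["buccal"], ages=[33.0])
        table = describe_cohort(manifest)
        assert np.isnan(table.loc["age_sd", "total"])

    def test_empty_manifest_errors(self):
        with pytest.raises(ConcordanceError):
            describe_cohort(pd.DataFrame(columns=["person_id"]))


def test_shared_aging_factor_recovered_within_ci():
    """Two tissues share a person-level factor of variance fraction rho;
    the cross-tissue r has ~95% CI coverage of rho across replicates."""
    rho, n, reps = 0.6, 50, 100
    rng = np.random.default_rng(20)
    covered = 0
    for _ in range(reps):
        f = rng.normal(size=n)
        ya = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.normal(size=n)
        yb = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.normal(size=n)
        r = np.corrcoef(ya, yb)[0, 1]
        z = np.arctanh(r)
        lo, hi = np.tanh(z - 1.96 / np.sqrt(n - 3)), np.tanh(z + 1.96 / np.sqrt(n - 3))
        covered += lo <= rho <= hi
    assert covered >= 90


def test_significance_stars_thresholds():
    assert stars(0.2) == ""
    assert stars(0.04) == "*"
    assert stars(0.009) == "**"
    assert stars(0.0009) == "***"
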