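"""Generator invariants: determinism, simplex truth, recoverable signals."""

import numpy as np
import pandas as pd
import pytest

from epiconcord.clocks import (
    acceleration_for,
    apply_clock,
    compute_acceleration,
    compute_estimates,
    horvath_age_transform,
)
from epiconcord.concordance import control_probe_pcs
from epiconcord.synthetic import (
    SimConfig,
    SimConfigError,
    generate_clock_definitions,
    generate_cohort,
)


def test_same_seed_reproduces_bitwise():
    cfg = SimConfig(n_children=3, n_adults=3, n_probes=300, n_age_probes=40, seed=5)
    b1, m1, c1, _ = generate_cohort(cfg)
    b2, m2, c2, _ = generate_cohort(cfg)
    pd.testing.assert_frame_equal(m1, m2)
    pd.testing.assert_frame_equal(c1, c2)
    for tissue in b1:
        pd.testing.assert_frame_equal(b1[tissue].values, b2[tissue].values)
        pd.testing.assert_frame_equal(b1[tissue].detection_p, b2[tissue].detection_p)


def test_zero_persons_rejected():
    with pytest.raises(SimConfigError):
        SimConfig(n_children=0, n_adults=0).validate()


def test_undefined_cell_type_count_rejected():
    with pytest.raises(SimConfigError):
        SimConfig(n_cell_types={"buccal": 3}).validate()


def test_degenerate_single_cell_type_equals_reference_plus_age_effect():
    """With no noise/batch and K=1, a sample IS the reference methylome
    (age probes carry the linear age effect)."""
    cfg = SimConfig(
        n_children=2,
        n_adults=2,
        n_probes=300,
        n_age_probes=40,
        noise_sd=0.0,
        batch_sd=0.0,
        n_cell_types={t: 1 for t in ("buccal", "saliva", "dbs", "buffy_coat", "pbmc")},
        seed=3,
    )
    betas, manifest, _, truth = generate_cohort(cfg)
    bm = betas["buccal"]
    meta = manifest.set_index("sample_id")
    ref = truth.cell_reference["buccal"].iloc[:, 0]
    age_ids = truth.age_probe_ids
    other = bm.probe_ids.difference(age_ids)
    for sid in bm.sample_ids:
        col = bm.values[sid]
        np.testing.assert_allclose(col[other], ref[other], atol=1e-12)
        t_cal = horvath_age_transform(float(meta.loc[sid, "age_years"]))
        expected = truth.age_baseline + truth.age_slope * t_cal
        np.testing.assert_allclose(col[age_ids], expected, atol=1e-12)


def test_study_sized_design_has_83_persons_with_cohort_tissues():
    cfg = SimConfig(n_children=36, n_adults=47, n_probes=120, n_age_probes=20, seed=1)
    _, manifest, _, _ = generate_cohort(cfg)
    assert manifest["person_id"].nunique() == 83
    child = manifest[manifest["cohort"] == "child"]
    adult = manifest[manifest["cohort"] == "adult"]
    assert set(child["tissue"]) == {"buccal", "saliva", "dbs", "buffy_coat"}
    assert set(adult["tissue"]) == {"buccal", "saliva", "dbs", "pbmc"}
    assert child["person_id"].nunique() == 36
    assert adult["person_id"].nunique() == 47


def test_truth_on_simplex_and_betas_in_range(small_cohort):
    betas, _, _, truth = small_cohort
    for tissue, props in truth.true_proportions.items():
        sums = props.to_numpy().sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
    for bm in betas.values():
        arr = bm.values.to_numpy()
        assert np.nanmin(arr) >= 0.0 and np.nanmax(arr) <= 1.0


def test_noiseless_linear_clock_recovers_true_age(noiseless_cohort, noiseless_clocks):
    betas, manifest, _, _ = noiseless_cohort
    linear = noiseless_clocks[0]
    ages = manifest.set_index("sample_id")["age_years"]
    for bm in betas.values():
        est = compute_estimates([linear], bm, manifest)
        err = (est.set_index("sample_id")["estimate"] - ages[est["sample_id"]]).abs()
        assert err.max() < 1e-6


def test_clock_error_increases_with_noise():
    """Mean absolute clock error is strictly monotone over a noise grid."""
    maes = []
    for noise in (0.02, 0.08, 0.3):
        cfg = SimConfig(
            n_children=5,
            n_adults=5,
            n_probes=400,
            n_age_probes=50,
            noise_sd=noise,
            batch_sd=0.0,
            tissues_children=("buccal",),
            tissues_adults=("buccal",),
            seed=11,
        )
        betas, manifest, _, truth = generate_cohort(cfg)
        linear = generate_clock_definitions(cfg, truth)[0]
        est = compute_estimates([linear], betas["buccal"], manifest)
        ages = manifest.set_index("sample_id")["age_years"]
        maes.append(
            float(
                (est.set_index("sample_id")["estimate"] - ages[est["sample_id"]])
                .abs()
                .mean()
            )
        )
    assert maes[0] < maes[1] < maes[2]


def test_batch_effect_separates_control_probe_pc1(small_cohort):
    from sklearn.metrics import silhouette_score

    _, manifest, controls, truth = small_cohort
    scores, _ = control_probe_pcs(controls, 1)
    labels = truth.batch_of[scores.index].to_numpy()
    sil = silhouette_score(scores.to_numpy(), labels)
    assert sil > 0


def test_rate_clock_refuses_acceleration(noiseless_cohort, noiseless_clocks):
    betas, manifest, _, _ = noiseless_cohort
    est = compute_estimates(noiseless_clocks, betas["buccal"], manifest)
    est = compute_acceleration(est, manifest)
    assert est.loc[est["clock"] == "sim_pace", "acceleration"].isna().all()
    with pytest.raises(Exception, match="rate"):
        acceleration_for(est, "sim_pace")


def test_pc_clock_returns_intercept_at_center(noiseless_clocks):
    pc = noiseless_clocks[2]
    assert pc.kind == "pc"
    assert apply_clock(pc, pc.center.copy()) == pytest.approx(pc.intercept, abs=1e-12)


def test_clock_definitions_serialize_round_trip(tmp_path, noiseless_clocks):
    from epiconcord.clocks import ClockDefinition

    rng = np.random.default_rng(0)
    for clock in noiseless_clocks:
        clock.to_dir(tmp_path / clock.name)
        loaded = ClockDefinition.from_dir(tmp_path / clock.name)
        probes = clock.required_probes
        beta = pd.Series(rng.uniform(0.1, 0.9, len(probes)), index=probes)
        assert apply_clock(loaded, beta) == pytest.approx(
            apply_clock(clock, beta), rel=1e-12
        )


def test_golden_standard_stratum_means(noiseless_cohort):
    from epiconcord.synthetic import generate_golden_standard

    betas, manifest, _, truth = noiseless_cohort
    golden = generate_golden_standard(betas, manifest, truth)
    child_ids = manifest.loc[
        (manifest["tissue"] == "buccal") & (manifest["cohort"] == "child"),
        "sample_id",
    ]
    expected = betas["buccal"].values[child_ids].mean(axis=1)
    np.testing.assert_allclose(
        golden.table[("buccal", "child")], expected, atol=1e-12
    )


def test_golden_standard_two_sample_mean():
    """Two samples with betas 0.2 / 0.4 average to 0.3; a probe missing
    everywhere in a stratum stays missing there."""
    from epiconcord.containers import BetaMatrix
    from epiconcord.imputation import build_golden_standard

    values = pd.DataFrame(
        {"s1": [0.2, np.nan], "s2": [0.4, np.nan]}, index=["cgA", "cgB"]
    )
    bm = BetaMatrix(values=values)
    manifest = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "person_id": ["p1", "p2"],
            "tissue": ["buccal", "buccal"],
            "age_years": [10.0, 12.0],
            "sex": ["F", "M"],
            "cohort": ["child", "child"],
            "plate": ["plate1", "plate1"],
            "bisulfite_rate": [0.95, 0.95],
        }
    )
    golden = build_golden_standard({"buccal": bm}, manifest)
    assert golden.table[("buccal", "child")]["cgA"] == pytest.approx(0.3)
    assert np.isnan(golden.table[("buccal", "child")]["cgB"])
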