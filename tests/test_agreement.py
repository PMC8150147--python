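"""Repeated-measures Bland–Altman statistics against hand and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stg

import statsmodels.formula.api as smf

from coagree import (
    AgreementOptions,
    SimulationConfig,
    analyze_agreement,
    bias_ci,
    differences,
    loa,
    loa_ci,
    percentage_error,
    percentage_error_ci,
    proportional_bias,
    simulate_cohort,
    variance_components,
)
from coagree.agreement import variance_components_of
from conftest import dataset_from_diffs, make_dataset, random_clustered_dataset


def brute_force_anova(diffs_by_patient):
    """Independent plain-loop one-way ANOVA of differences."""
    all_d = [d for ds in diffs_by_patient for d in ds]
    n = len(all_d)
    k = len(diffs_by_patient)
    grand = sum(all_d) / n
    means = [sum(ds) / len(ds) for ds in diffs_by_patient]
    ssb = sum(len(ds) * (m - grand) ** 2 for ds, m in zip(diffs_by_patient, means))
    ssw = sum((d - m) ** 2 for ds, m in zip(diffs_by_patient, means) for d in ds)
    msb = ssb / (k - 1)
    msw = ssw / (n - k) if n > k else 0.0
    n0 = (n**2 - sum(len(ds) ** 2 for ds in diffs_by_patient)) / ((k - 1) * n)
    s2b = max(0.0, (msb - msw) / n0)
    return grand, msb, msw, n0, s2b, msw, np.sqrt(s2b + msw)


# ---------------------------------------------------------------------------
# differences
# ---------------------------------------------------------------------------

def test_difference_and_mean_arithmetic():
    ds = make_dataset([("A", 0, "other", 2.0, 2.5), ("A", 1, "other", 2.2, 2.2),
                       ("B", 0, "other", 3.0, 2.4)])
    dm = differences(ds)
    np.testing.assert_allclose(dm["diff"], [0.5, 0.0, -0.6])
    np.testing.assert_allclose(dm["mean"], [2.25, 2.2, 2.7])


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

def test_hand_worked_anova():
    """Patient A diffs {0,2}, B diffs {−1,1}: d̄ 0.5, MSB 1, MSW 2, n0 2,
    between truncates to 0, sd_total √2."""
    ds = dataset_from_diffs({"A": [0.0, 2.0], "B": [-1.0, 1.0]})
    vc = variance_components_of(ds)
    assert vc.grand_mean_diff == pytest.approx(0.5)
    assert vc.ms_between == pytest.approx(1.0)
    assert vc.ms_within == pytest.approx(2.0)
    assert vc.n0 == pytest.approx(2.0)
    assert vc.sigma2_between == 0.0
    assert vc.truncated
    assert vc.sd_total == pytest.approx(np.sqrt(2.0))


def test_single_measurement_per_patient_is_sample_sd():
    vc = variance_components([1.0, 2.0, 3.0], ["a", "b", "c"])
    assert vc.sd_total == pytest.approx(1.0, abs=1e-15)
    assert vc.sigma2_within == 0.0
    assert vc.n0 == pytest.approx(1.0)


def test_constant_differences():
    vc = variance_components([0.3, 0.3, 0.3, 0.3], ["a", "a", "b", "b"])
    assert vc.grand_mean_diff == pytest.approx(0.3)
    assert vc.sd_total == 0.0


def test_fewer_than_two_patients_rejected():
    with pytest.raises(ValueError, match="2 patients"):
        variance_components([0.1, 0.2], ["a", "a"])


@pytest.mark.parametrize("seed", range(25))
def test_variance_components_vs_brute_force(seed):
    rng = np.random.default_rng(seed)
    k = rng.integers(2, 7)
    groups = [list(rng.normal(0, 1, rng.integers(1, 8))) for _ in range(k)]
    diffs = [d for g in groups for d in g]
    pats = [i for i, g in enumerate(groups) for _ in g]
    vc = variance_components(diffs, pats)
    grand, msb, msw, n0, s2b, s2w, sd = brute_force_anova(groups)
    np.testing.assert_allclose(
        [vc.grand_mean_diff, vc.ms_between, vc.ms_within, vc.n0,
         vc.sigma2_between, vc.sigma2_within, vc.sd_total],
        [grand, msb, msw, n0, s2b, s2w, sd],
        rtol=1e-10, atol=1e-12,
    )


def test_mean_squares_match_statsmodels_anova():
    """Cross-check MS_between / MS_within against an OLS ANOVA table."""
    rng = np.random.default_rng(42)
    groups = [list(rng.normal(0, 1, m)) for m in (3, 5, 4, 7)]
    diffs = [d for g in groups for d in g]
    pats = [f"p{i}" for i, g in enumerate(groups) for _ in g]
    vc = variance_components(diffs, pats)
    import pandas as pd
    import statsmodels.api as sm
    df = pd.DataFrame({"d": diffs, "p": pats})
    table = sm.stats.anova_lm(smf.ols("d ~ C(p)", data=df).fit())
    np.testing.assert_allclose(vc.ms_between, table["mean_sq"]["C(p)"], rtol=1e-10)
    np.testing.assert_allclose(vc.ms_within, table["mean_sq"]["Residual"], rtol=1e-10)


# ---------------------------------------------------------------------------
# LOA and CIs
# ---------------------------------------------------------------------------

def test_loa_arithmetic():
    ds = dataset_from_diffs({"A": [0.0, 2.0], "B": [-1.0, 1.0]})
    vc = variance_components_of(ds)
    lo, up = loa(vc)
    assert lo == pytest.approx(0.5 - 1.96 * np.sqrt(2))
    assert up == pytest.approx(0.5 + 1.96 * np.sqrt(2))
    lo0, up0 = loa(vc, z=0.0)
    assert lo0 == up0 == pytest.approx(0.5)


def test_bias_ci_collapses_to_within_term_when_between_zero():
    """Patients with identical means: σ²_b truncates to 0 and the CI is
    d̄ ± t·sd_within/√N."""
    ds = dataset_from_diffs({"A": [-1.0, 1.0], "B": [-2.0, 2.0]}, base=3.0)
    vc = variance_components_of(ds)
    assert vc.sigma2_between == 0.0
    import scipy.stats as st
    expected_half = st.t.ppf(0.975, 1) * np.sqrt(vc.sigma2_within / 4)
    lo, hi = bias_ci(vc)
    assert hi - vc.grand_mean_diff == pytest.approx(expected_half)
    assert vc.grand_mean_diff - lo == pytest.approx(expected_half)


def test_zero_variance_gives_zero_width_cis():
    vc = variance_components([0.2] * 6, ["a", "a", "b", "b", "c", "c"])
    lo, hi = bias_ci(vc)
    assert lo == pytest.approx(0.2, abs=1e-12)
    assert hi == pytest.approx(0.2, abs=1e-12)
    # exactly-zero differences additionally trigger the degeneracy warning
    vc0 = variance_components([0.0] * 4, ["a", "a", "b", "b"])
    with pytest.warns(UserWarning):
        lci, uci = loa_ci(vc0)
    assert lci == (0.0, 0.0) and uci == (0.0, 0.0)


def test_loa_ci_delta_and_mover_agree_asymptotically():
    """For a large balanced cohort the two CI constructions agree within
    10% of interval width."""
    ds = simulate_cohort(SimulationConfig(n_patients=200,
                                          measurements_per_patient=30, seed=8))
    vc = variance_components_of(ds)
    for side in (0, 1):
        m = loa_ci(vc, method="mover")[side]
        d = loa_ci(vc, method="delta")[side]
        width = m[1] - m[0]
        assert abs(m[0] - d[0]) < 0.1 * width
        assert abs(m[1] - d[1]) < 0.1 * width


def test_loa_ci_single_measurement_matches_classical():
    """With one measurement per patient the MOVER CI width matches the
    classical Bland–Altman SE(LOA) = sd·√(3/N) within 5%."""
    rng = np.random.default_rng(0)
    n = 500
    d = rng.normal(0.1, 0.7, n)
    vc = variance_components(d, [f"p{i}" for i in range(n)])
    import scipy.stats as st
    classical_width = 2 * st.norm.ppf(0.975) * vc.sd_total * np.sqrt(3.0 / n)
    lci, uci = loa_ci(vc, method="mover")
    for ci in (lci, uci):
        assert (ci[1] - ci[0]) == pytest.approx(classical_width, rel=0.05)


# ---------------------------------------------------------------------------
# percentage error
# ---------------------------------------------------------------------------

def test_percentage_error_at_critchley_threshold():
    """z·sd = 0.6 against a reference mean of 2.0 is exactly 30%."""
    sd = 0.6 / 1.96
    ds = dataset_from_diffs({"A": [sd, -sd], "B": [sd, -sd]}, base=2.0)
    # differences {±sd} have sample statistics we don't need: build vc directly
    vc = variance_components_of(ds)
    # force the exact sd via a crafted component set
    vc = type(vc)(**{**vc.__dict__, "sigma2_between": 0.0,
                     "sigma2_within": sd**2, "sd_total": sd})
    assert percentage_error(vc, ds) == pytest.approx(
        100 * 0.6 / ds.frame["ci_ref"].mean())


def test_percentage_error_scale_invariance(default_cohort):
    vc = variance_components_of(default_cohort)
    pe = percentage_error(vc, default_cohort)
    scaled = make_dataset(
        [(r.patient_id, r.time_index, r.phase, 3.7 * r.ci_ref, 3.7 * r.ci_test)
         for r in default_cohort.frame.itertuples()]
    )
    vc_s = variance_components_of(scaled)
    assert percentage_error(vc_s, scaled) == pytest.approx(pe, rel=1e-10)


def test_percentage_error_ci_deterministic_and_contains_point(default_cohort):
    vc = variance_components_of(default_cohort)
    pe = percentage_error(vc, default_cohort)
    a = percentage_error_ci(default_cohort, B=200, seed=5)
    b = percentage_error_ci(default_cohort, B=200, seed=5)
    assert a == b
    assert a[0] < pe < a[1]


def test_percentage_error_ci_zero_sd():
    ds = dataset_from_diffs({"A": [0.0, 0.0], "B": [0.0, 0.0]})
    assert percentage_error_ci(ds, B=50, seed=1) == (0.0, 0.0)


# ---------------------------------------------------------------------------
# proportional bias
# ---------------------------------------------------------------------------

def test_proportional_bias_exact_linear_fit():
    rows = []
    for i, pid in enumerate(["A", "B"]):
        for t in range(3):
            mean = 2.0 + 0.3 * t + 0.05 * i
            d = 0.5 * mean  # difference exactly linear in the mean
            rows.append((pid, t, "other", mean - d / 2, mean + d / 2))
    ds = make_dataset(rows)
    res = proportional_bias(ds)
    assert res.slope == pytest.approx(0.5, abs=1e-10)
    assert res.slope_ci[1] - res.slope_ci[0] == pytest.approx(0.0, abs=1e-8)


def test_proportional_bias_slope_ignores_patient_labels():
    rng = np.random.default_rng(3)
    ds = random_clustered_dataset(rng)
    res = proportional_bias(ds)
    shuffled = ds.frame.copy()
    ids = shuffled["patient_id"].to_numpy().copy()
    rng.shuffle(ids)
    shuffled["patient_id"] = ids
    shuffled["time_index"] = range(len(shuffled))  # avoid duplicate keys
    from coagree import CohortDataset
    res2 = proportional_bias(CohortDataset(frame=shuffled))
    assert res2.slope == pytest.approx(res.slope, rel=1e-10)


def test_proportional_bias_recovers_generator_slope():
    """The OLS slope at large n matches a Monte-Carlo regression oracle run
    on an independent draw from the same generator."""
    cfg = SimulationConfig(n_patients=1500, measurements_per_patient=30, seed=21)
    ds = simulate_cohort(cfg)
    res = proportional_bias(ds)
    oracle_ds = simulate_cohort(
        SimulationConfig(n_patients=1500, measurements_per_patient=30, seed=22))
    dm = differences(oracle_ds)
    slope_oracle = np.polyfit(dm["mean"], dm["diff"], 1)[0]
    assert res.slope == pytest.approx(slope_oracle, abs=0.05)


def test_proportional_bias_zero_mean_variance_errors():
    ds = dataset_from_diffs({"A": [0.0, 0.0], "B": [0.0, 0.0]})
    with pytest.raises(ValueError, match="zero variance"):
        proportional_bias(ds)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def test_analyze_agreement_row_structure(default_cohort):
    res = analyze_agreement(
        default_cohort,
        phases=("baseline", "aortic_side_clamp", "distal_anastomoses",
                "icu_pre_extubation"),
        options=AgreementOptions(bootstrap_b=100),
    )
    assert [r.phase for r in res] == [
        "all", "baseline", "aortic_side_clamp", "distal_anastomoses",
        "icu_pre_extubation"]
    for r in res:
        assert r.loa_lower <= r.bias <= r.loa_upper
        assert r.bias_ci[0] <= r.bias <= r.bias_ci[1]


def test_analyze_agreement_noiseless_devices():
    ds = dataset_from_diffs({"A": [0.0, 0.0], "B": [0.0, 0.0]})
    r = analyze_agreement(ds, options=AgreementOptions(bootstrap_b=50))[0]
    assert r.bias == 0.0
    assert (r.loa_lower, r.loa_upper) == (0.0, 0.0)
    assert r.percentage_error == 0.0


def test_single_patient_phase_flagged_insufficient():
    ds = make_dataset([
        ("A", 0, "baseline", 2.0, 2.2),
        ("A", 1, "other", 2.1, 2.3),
        ("B", 0, "other", 2.5, 2.4),
        ("B", 1, "other", 2.6, 2.8),
    ])
    res = analyze_agreement(ds, phases=("baseline",),
                            options=AgreementOptions(bootstrap_b=50))
    base = [r for r in res if r.phase == "baseline"][0]
    assert base.insufficient
    assert base.bias_ci is None and base.loa_lower_ci is None


@settings(max_examples=30, deadline=None, derandomize=True)
@given(stg.integers(min_value=0, max_value=10_000))
def test_loa_symmetry_property(seed):
    """LOA are symmetric about the bias with width 2·z·sd for any dataset."""
    rng = np.random.default_rng(seed)
    ds = random_clustered_dataset(rng)
    if ds.frame["patient_id"].nunique() < 2:
        return
    vc = variance_components_of(ds)
    lo, up = loa(vc)
    assert up - vc.grand_mean_diff == pytest.approx(vc.grand_mean_diff - lo)
    assert up - lo == pytest.approx(2 * 1.96 * vc.sd_total)
    assert vc.sigma2_between >= 0.0
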