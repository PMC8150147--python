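"""Repeated-measures Bland–Altman agreement statistics.

Implements the variant of Bland–Altman analysis appropriate when each
subject contributes multiple paired measurements and the underlying true
value varies within the subject: the variance of the paired differences
is decomposed by one-way ANOVA with patient as the factor, and the
limits of agreement (LOA) are built from the total (between- plus
within-patient) standard deviation.  Confidence intervals for the LOA
use either a MOVER/modified-large-sample construction on the variance
components (default; better small-sample coverage) or a first-order
delta method.  Percentage error follows the Critchley convention
(1.96·SD over the mean reference CI) with a patient-level cluster
bootstrap for its CI, and proportional bias is the OLS slope of the
difference on the pairwise mean with patient-clustered standard errors.

Sign convention throughout: difference = test − reference, so a
positive bias means the test device overestimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .measurements import CohortDataset, filter_phase

__all__ = [
    "VarianceComponents",
    "AgreementResult",
    "PropBiasResult",
    "differences",
    "variance_components",
    "loa",
    "bias_ci",
    "loa_ci",
    "percentage_error",
    "percentage_error_ci",
    "proportional_bias",
    "analyze_agreement",
]


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceComponents:
    """One-way ANOVA decomposition of paired-difference variance.

    ``grand_mean_diff`` is the bias d̄; ``sd_total`` is the SD entering
    the limits of agreement, sqrt(sigma2_between + sigma2_within).
    ``truncated`` flags a negative raw between-patient estimate that was
    clipped to zero (standard ANOVA-estimator practice).
    """

    k: int
    n_total: int
    m_i: tuple[int, ...]
    grand_mean_diff: float
    ms_between: float
    ms_within: float
    n0: float
    sigma2_between: float
    sigma2_within: float
    sd_total: float
    truncated: bool = False


def differences(dataset: CohortDataset) -> pd.DataFrame:
    """Per-measurement difference (test − ref) and pairwise mean, by patient."""
    if dataset.n_measurements == 0:
        raise ValueError("empty dataset: no paired measurements")
    df = dataset.frame
    return pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "diff": df["ci_test"] - df["ci_ref"],
            "mean": (df["ci_test"] + df["ci_ref"]) / 2.0,
        }
    )


def variance_components(
    diffs: Sequence[float] | np.ndarray,
    patients: Sequence,
) -> VarianceComponents:
    """One-way ANOVA of differences with patient as the grouping factor.

    SS_between = Σ mᵢ(d̄ᵢ − d̄)² on k−1 df; SS_within = Σ (dᵢⱼ − d̄ᵢ)² on
    N−k df; n0 = (N² − Σmᵢ²)/((k−1)N); sigma2_within = MS_within;
    sigma2_between = max(0, (MS_between − MS_within)/n0).  When every
    patient contributes a single measurement the within df is zero,
    n0 = 1 and sd_total degenerates to the ordinary sample SD.
    """
    d = np.asarray(diffs, dtype=float)
    codes, _ = pd.factorize(np.asarray(patients))
    if d.shape[0] != codes.shape[0]:
        raise ValueError("diffs and patients must have equal length")
    k = int(codes.max()) + 1 if len(codes) else 0
    if k < 2:
        raise ValueError(
            "variance components need >= 2 patients (between component undefined)"
        )
    n = len(d)
    m = np.bincount(codes, minlength=k).astype(float)
    sums = np.bincount(codes, weights=d, minlength=k)
    means = sums / m
    grand = float(d.mean())

    ss_between = float(m @ (means - grand) ** 2)
    ss_within = float(((d - means[codes]) ** 2).sum())
    ms_between = ss_between / (k - 1)
    df_within = n - k
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (n**2 - float(m @ m)) / ((k - 1) * n)

    sigma2_within = ms_within
    raw_between = (ms_between - ms_within) / n0
    truncated = raw_between < 0
    sigma2_between = max(0.0, raw_between)
    sd_total = float(np.sqrt(sigma2_between + sigma2_within))
    return VarianceComponents(
        k=k,
        n_total=n,
        m_i=tuple(int(x) for x in m),
        grand_mean_diff=grand,
        ms_between=ms_between,
        ms_within=ms_within,
        n0=n0,
        sigma2_between=sigma2_between,
        sigma2_within=sigma2_within,
        sd_total=sd_total,
        truncated=bool(truncated),
    )


def variance_components_of(dataset: CohortDataset) -> VarianceComponents:
    """Convenience: :func:`variance_components` on a dataset's differences."""
    dm = differences(dataset)
    return variance_components(dm["diff"].to_numpy(), dm["patient_id"].to_numpy())


# ---------------------------------------------------------------------------
# limits of agreement and their confidence intervals
# ---------------------------------------------------------------------------

def loa(vc: VarianceComponents, z: float = 1.96) -> tuple[float, float]:
    """Limits of agreement: bias ∓ z·sd_total (z fixed at 1.96 by convention)."""
    return (
        vc.grand_mean_diff - z * vc.sd_total,
        vc.grand_mean_diff + z * vc.sd_total,
    )


def _var_mean(vc: VarianceComponents) -> float:
    m2 = float(np.asarray(vc.m_i, dtype=float) @ np.asarray(vc.m_i, dtype=float))
    return (vc.sigma2_between * m2 + vc.sigma2_within * vc.n_total) / vc.n_total**2


def bias_ci(vc: VarianceComponents, level: float = 0.95) -> tuple[float, float]:
    """t-based CI for the bias, Var(d̄) = (σ²_b·Σmᵢ² + σ²_w·N)/N², k−1 df."""
    se = float(np.sqrt(_var_mean(vc)))
    tcrit = st.t.ppf((1 + level) / 2, vc.k - 1)
    return (vc.grand_mean_diff - tcrit * se, vc.grand_mean_diff + tcrit * se)


def _variance_mls_ci(
    vc: VarianceComponents, level: float
) -> tuple[float, float]:
    """Modified-large-sample CI for sd_total² = (1/n0)·MS_b + (1−1/n0)·MS_w.

    Each mean square gets exact chi-square limits on its own df
    (Lᵢ = dfᵢ·MSᵢ/χ²_{1−α/2}, Uᵢ = dfᵢ·MSᵢ/χ²_{α/2}); the component
    half-widths are combined by square-and-add around the point value
    (Graybill–Wang construction, the variance step of the
    repeated-measures MOVER interval).
    """
    alpha = 1 - level
    comps = [(1.0 / vc.n0, vc.ms_between, vc.k - 1)]
    if vc.n_total - vc.k > 0 and vc.n0 > 1:
        comps.append((1.0 - 1.0 / vc.n0, vc.ms_within, vc.n_total - vc.k))
    point = sum(c * ms for c, ms, _ in comps)
    lo_sq = hi_sq = 0.0
    for c, ms, df in comps:
        if df <= 0 or c == 0 or ms == 0:
            continue
        l_i = df * ms / st.chi2.ppf(1 - alpha / 2, df)
        u_i = df * ms / st.chi2.ppf(alpha / 2, df)
        lo_sq += (c * (ms - l_i)) ** 2
        hi_sq += (c * (u_i - ms)) ** 2
    lower = max(0.0, point - float(np.sqrt(lo_sq)))
    upper = point + float(np.sqrt(hi_sq))
    return lower, upper


def _var_sd_total(vc: VarianceComponents) -> float:
    """Delta-method Var(sd_total): Var(s²)/(4s²), Var(MS) = 2·MS²/df."""
    if vc.sd_total == 0:
        return 0.0
    var_s2 = (1.0 / vc.n0) ** 2 * 2 * vc.ms_between**2 / (vc.k - 1)
    df_w = vc.n_total - vc.k
    if df_w > 0 and vc.n0 > 1:
        var_s2 += (1 - 1.0 / vc.n0) ** 2 * 2 * vc.ms_within**2 / df_w
    return var_s2 / (4 * vc.sd_total**2)


def loa_ci(
    vc: VarianceComponents,
    level: float = 0.95,
    method: Literal["mover", "delta"] = "mover",
    z: float = 1.96,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """CIs for (lower LOA, upper LOA).

    ``mover``: combine the t-based bias CI with the square-root of the
    modified-large-sample variance CI by the MOVER square-and-add rule
    around each limit.  ``delta``: normal interval with
    Var(limit) ≈ Var(d̄) + z²·Var(sd_total).
    """
    lo, up = loa(vc, z=z)
    if vc.sd_total == 0:
        warnings.warn("sd_total is zero: LOA confidence intervals are degenerate")
        return ((lo, lo), (up, up))
    if method == "delta":
        zcrit = st.norm.ppf((1 + level) / 2)
        se = float(np.sqrt(_var_mean(vc) + z**2 * _var_sd_total(vc)))
        return ((lo - zcrit * se, lo + zcrit * se),
                (up - zcrit * se, up + zcrit * se))
    if method != "mover":
        raise ValueError(f"unknown LOA-CI method {method!r}")

    # Mean component with normal limits (the MOVER convention; the
    # standalone bias CI stays t-based).
    w_mean = st.norm.ppf((1 + level) / 2) * float(np.sqrt(_var_mean(vc)))
    var_lo, var_hi = _variance_mls_ci(vc, level)
    s = vc.sd_total
    s_lo, s_hi = float(np.sqrt(var_lo)), float(np.sqrt(var_hi))
    # Half-widths of the two independent pieces, square-and-add per limit.
    w_mean_lo, w_mean_hi = w_mean, w_mean
    w_s_lo, w_s_hi = z * (s - s_lo), z * (s_hi - s)
    upper_ci = (
        up - float(np.hypot(w_mean_lo, w_s_lo)),
        up + float(np.hypot(w_mean_hi, w_s_hi)),
    )
    lower_ci = (
        lo - float(np.hypot(w_mean_lo, w_s_hi)),
        lo + float(np.hypot(w_mean_hi, w_s_lo)),
    )
    return lower_ci, upper_ci


# ---------------------------------------------------------------------------
# percentage error
# ---------------------------------------------------------------------------

def _pe_denominator(
    dataset: CohortDataset, denominator: Literal["reference", "both"]
) -> float:
    df = dataset.frame
    if denominator == "reference":
        return float(df["ci_ref"].mean())
    if denominator == "both":
        return float(((df["ci_ref"] + df["ci_test"]) / 2.0).mean())
    raise ValueError(f"unknown PE denominator {denominator!r}")


def percentage_error(
    vc: VarianceComponents,
    dataset: CohortDataset,
    z: float = 1.96,
    denominator: Literal["reference", "both"] = "reference",
) -> float:
    """Percentage error, 100·z·sd_total / mean CI.

    The Critchley interchangeability screen compares this against 30%.
    The denominator is the mean reference CI by default ("both" uses the
    mean of pairwise means); the caller should record the choice.
    """
    denom = _pe_denominator(dataset, denominator)
    if denom <= 0:
        raise ValueError("non-positive mean CI in percentage-error denominator")
    return 100.0 * z * vc.sd_total / denom


def percentage_error_ci(
    dataset: CohortDataset,
    level: float = 0.95,
    B: int = 2000,
    seed: int | np.random.Generator = 0,
    z: float = 1.96,
    denominator: Literal["reference", "both"] = "reference",
) -> tuple[float, float]:
    """Percentile CI for the percentage error by patient-cluster bootstrap.

    Patients are resampled with replacement (resampled copies count as
    distinct clusters, preserving k) and the full PE pipeline is
    recomputed per replicate.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    dm = differences(dataset)
    codes, _ = pd.factorize(dm["patient_id"].to_numpy())
    k = codes.max() + 1
    if k < 2:
        raise ValueError("percentage-error bootstrap needs >= 2 patients")
    d = dm["diff"].to_numpy()
    if denominator == "reference":
        vals = dataset.frame["ci_ref"].to_numpy()
    else:
        vals = dm["mean"].to_numpy()
    per_d = [d[codes == i] for i in range(k)]
    per_v = [vals[codes == i] for i in range(k)]

    pes = np.empty(B)
    for b in range(B):
        take = rng.integers(0, k, size=k)
        db = np.concatenate([per_d[i] for i in take])
        vb = np.concatenate([per_v[i] for i in take])
        cb = np.repeat(np.arange(k), [len(per_d[i]) for i in take])
        vcb = variance_components(db, cb)
        pes[b] = 100.0 * z * vcb.sd_total / vb.mean()
    alpha = 1 - level
    lo, hi = np.percentile(pes, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# proportional bias
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropBiasResult:
    """OLS of difference on pairwise mean with patient-clustered SEs."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    slope_se: float


def proportional_bias(dataset: CohortDataset, level: float = 0.95) -> PropBiasResult:
    """Regress difference on pairwise mean to detect magnitude-dependent bias.

    The slope is reported unstandardized, sign preserved; its CI uses
    cluster-robust (patient-clustered) standard errors with a t
    reference on k−1 df, since repeated measurements within a patient
    are correlated.
    """
    dm = differences(dataset)
    if len(dm) < 3 or dm["patient_id"].nunique() < 2:
        raise ValueError("proportional bias needs >= 3 measurements and >= 2 patients")
    x = dm["mean"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("pairwise means have zero variance; slope undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(dm["diff"].to_numpy(), X).fit(
        cov_type="cluster",
        cov_kwds={"groups": dm["patient_id"].to_numpy()},
        use_t=True,
    )
    ci = fit.conf_int(alpha=1 - level)
    return PropBiasResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        slope_se=float(fit.bse[1]),
    )


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    """Bias, LOA, percentage error and proportional bias for one device/phase.

    Mirrors one column of a method-comparison summary table.  When a
    phase has fewer than two patients the estimate row is flagged
    ``insufficient`` and all CIs are None.
    """

    device: str
    phase: str
    n: int
    n_patients: int
    bias: float
    bias_ci: tuple[float, float] | None
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple[float, float] | None
    loa_upper_ci: tuple[float, float] | None
    percentage_error: float
    percentage_error_ci: tuple[float, float] | None
    prop_bias_slope: float | None
    prop_bias_ci: tuple[float, float] | None
    sd_total: float
    insufficient: bool = False
    options: dict = field(default_factory=dict)


@dataclass(frozen=True)
class AgreementOptions:
    """Tunable knobs of the agreement chain, echoed into every result."""

    z: float = 1.96
    level: float = 0.95
    pe_denominator: Literal["reference", "both"] = "reference"
    loa_ci_method: Literal["mover", "delta"] = "mover"
    bootstrap_b: int = 2000
    seed: int = 0


def _analyze_one(
    dataset: CohortDataset, phase: str, opts: AgreementOptions
) -> AgreementResult:
    dm = differences(dataset)
    d = dm["diff"].to_numpy()
    n = len(d)
    k = dm["patient_id"].nunique()
    echo = {
        "z": opts.z,
        "level": opts.level,
        "pe_denominator": opts.pe_denominator,
        "loa_ci_method": opts.loa_ci_method,
        "bootstrap_b": opts.bootstrap_b,
        "seed": opts.seed,
        "sign_convention": "test_minus_reference",
    }
    if k < 2:
        bias = float(d.mean())
        sd = float(d.std(ddof=1)) if n > 1 else 0.0
        denom = _pe_denominator(dataset, opts.pe_denominator)
        return AgreementResult(
            device=dataset.device_name, phase=phase, n=n, n_patients=k,
            bias=bias, bias_ci=None,
            loa_lower=bias - opts.z * sd, loa_upper=bias + opts.z * sd,
            loa_lower_ci=None, loa_upper_ci=None,
            percentage_error=100.0 * opts.z * sd / denom,
            percentage_error_ci=None,
            prop_bias_slope=None, prop_bias_ci=None,
            sd_total=sd, insufficient=True, options=echo,
        )
    vc = variance_components(d, dm["patient_id"].to_numpy())
    lo, up = loa(vc, z=opts.z)
    lo_ci, up_ci = loa_ci(vc, level=opts.level, method=opts.loa_ci_method, z=opts.z)
    pe = percentage_error(vc, dataset, z=opts.z, denominator=opts.pe_denominator)
    pe_ci = percentage_error_ci(
        dataset, level=opts.level, B=opts.bootstrap_b, seed=opts.seed,
        z=opts.z, denominator=opts.pe_denominator,
    )
    try:
        pb = proportional_bias(dataset, level=opts.level)
        slope, slope_ci = pb.slope, pb.slope_ci
    except ValueError:
        slope, slope_ci = None, None
    return AgreementResult(
        device=dataset.device_name, phase=phase, n=n, n_patients=k,
        bias=vc.grand_mean_diff, bias_ci=bias_ci(vc, level=opts.level),
        loa_lower=lo, loa_upper=up,
        loa_lower_ci=lo_ci, loa_upper_ci=up_ci,
        percentage_error=pe, percentage_error_ci=pe_ci,
        prop_bias_slope=slope, prop_bias_ci=slope_ci,
        sd_total=vc.sd_total, insufficient=False, options=echo,
    )


def analyze_agreement(
    dataset: CohortDataset,
    phases: Sequence[str] | Literal["all"] = "all",
    options: AgreementOptions | None = None,
) -> list[AgreementResult]:
    """Run the full agreement chain on the whole cohort and each phase.

    Returns one :class:`AgreementResult` for "all" plus one per requested
    phase (in order).  ``phases="all"`` analyzes only the pooled data.
    """
    opts = options or AgreementOptions()
    results = [_analyze_one(dataset, "all", opts)]
    if phases != "all":
        for ph in phases:
            sub = filter_phase(dataset, ph)
            if sub.n_measurements == 0:
                continue
            results.append(_analyze_one(sub, ph, opts))
    return results
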