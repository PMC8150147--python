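"""Seeded generator of OPCAB-like paired cardiac-index series.

The generator emulates the structure of a beating-heart bypass
monitoring cohort — 20 patients, ~29 simultaneous thermodilution /
test-device CI readings each across four named clinical phases — with a
fully known bias and variance structure, so that every downstream
agreement statistic has a parameter-recovery oracle.

Model, per patient i and timepoint j:

    T_i     ~ Normal(patient_mean_ci, patient_sd²)          patient level
    a_ij    = ar_coefficient·a_i,j−1 + innovation            AR(1), started
              innovation ~ Normal(0, innovation_sd²)         at stationarity
    t_ij    = max(0.5, T_i + phase_effect(phase_ij) + a_ij)  latent true CI

    ci_ref  = t_ij·(1 + ε),  ε ~ Normal(0, ref_cv²)          multiplicative:
                                                             thermodilution
                                                             precision is
                                                             quoted as ±20%,
                                                             i.e. CV ≈ 0.10
    ci_test = t_ij + test_bias0
              + test_bias1·(t_ij − patient_mean_ci)
              + u_i + η,   u_i ~ Normal(0, test_patient_sd²)
                           η   ~ Normal(0, test_noise_sd²)   additive, to
                                                             match the bias/
                                                             LOA scale

Both observed series are floored at small positive values (0.1) far
below physiological interest, preserving determinism and row counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .measurements import DEFAULT_PHASES, CohortDataset

#: Per-patient phase counts mirroring the study's phase sizes
#: (24/27/85/104 of 579 over 20 patients → roughly 1/1/4/5 per patient),
#: the remainder being ordinary OR/ICU readings.
DEFAULT_PHASE_COUNTS: dict[str, int] = {
    "baseline": 1,
    "aortic_side_clamp": 1,
    "distal_anastomoses": 4,
    "icu_pre_extubation": 5,
    "other": 18,
}

_TRUE_FLOOR = 0.5
_OBS_FLOOR = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of the synthetic cohort.

    Units are L·min⁻¹·m⁻² unless noted.  Defaults reproduce the study
    conditions: 20 patients, 29 paired readings each, mean reference CI
    2.4, thermodilution CV 0.10 (±20% precision), and a test device with
    constant bias 0.13, proportional bias 0.3 per unit CI above the
    cohort mean, a patient-level offset (SD 0.3) and reading noise
    (SD 0.5).
    """

    n_patients: int = 20
    measurements_per_patient: int | Mapping[str, int] = 29
    patient_mean_ci: float = 2.4
    patient_sd: float = 0.4
    ar_coefficient: float = 0.8
    innovation_sd: float = 0.25
    phase_effects: Mapping[str, float] = field(
        default_factory=lambda: {"distal_anastomoses": -0.3}
    )
    ref_cv: float = 0.10
    test_bias0: float = 0.13
    test_bias1: float = 0.3
    test_patient_sd: float = 0.3
    test_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if isinstance(self.measurements_per_patient, int):
            if self.measurements_per_patient < 1:
                raise ValueError("measurements_per_patient must be >= 1")
        else:
            counts = dict(self.measurements_per_patient)
            if any(v < 0 for v in counts.values()) or sum(counts.values()) < 1:
                raise ValueError("per-phase counts must be >= 0 and total >= 1")
            unknown = set(counts) - set(DEFAULT_PHASES)
            if unknown:
                raise ValueError(f"unknown phase(s) in counts: {sorted(unknown)}")
        for name in ("patient_sd", "innovation_sd", "ref_cv",
                     "test_patient_sd", "test_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.patient_mean_ci <= 0:
            raise ValueError("patient_mean_ci must be > 0")

    def phase_counts(self) -> dict[str, int]:
        """Resolved per-phase counts for one patient."""
        if isinstance(self.measurements_per_patient, Mapping):
            return {p: int(self.measurements_per_patient.get(p, 0))
                    for p in DEFAULT_PHASES}
        return _counts_from_total(int(self.measurements_per_patient))

    def phase_sequence(self) -> list[str]:
        """Protocol-ordered phase label per timepoint for one patient.

        Baseline first, then OR readings with the side-clamp and distal
        anastomosis phases embedded, ICU pre-extubation readings last.
        """
        c = self.phase_counts()
        first_or = c["other"] // 2
        seq = (
            ["baseline"] * c["baseline"]
            + ["other"] * first_or
            + ["aortic_side_clamp"] * c["aortic_side_clamp"]
            + ["distal_anastomoses"] * c["distal_anastomoses"]
            + ["other"] * (c["other"] - first_or)
            + ["icu_pre_extubation"] * c["icu_pre_extubation"]
        )
        return seq


def _counts_from_total(m: int) -> dict[str, int]:
    named = {k: v for k, v in DEFAULT_PHASE_COUNTS.items() if k != "other"}
    n_named = sum(named.values())  # 11
    if m >= n_named + 1:
        return {**named, "other": m - n_named}
    # Short series: fill named phases in protocol order until m is spent.
    counts = dict.fromkeys(DEFAULT_PHASES, 0)
    order = ["baseline", "aortic_side_clamp"] + \
        ["distal_anastomoses"] * named["distal_anastomoses"] + \
        ["icu_pre_extubation"] * named["icu_pre_extubation"]
    for label in order[:m]:
        counts[label] += 1
    return counts


@dataclass(frozen=True)
class ExpectedAgreement:
    """Closed-form bias and difference-variance decomposition of a config.

    ``bias`` is E[ci_test − ci_ref].  The variance of a single difference
    splits into a between-patient component (patient-level device offset
    plus proportional bias acting on the patient effect) and a
    within-patient component (proportional bias acting on the AR and
    phase variation, test-device reading noise, and reference noise
    scaled by E[t²]).
    """

    bias: float
    sigma2_between: float
    sigma2_within: float

    @property
    def sd_total(self) -> float:
        return float(np.sqrt(self.sigma2_between + self.sigma2_within))


def expected_agreement(config: SimulationConfig) -> ExpectedAgreement:
    """Analytic agreement statistics implied by the generator.

    Truncation at the floors is ignored (it is a ~1e-10 tail event at
    the default noise levels).  Term by term, with t the latent true CI,
    μ = patient_mean_ci, b0/b1 the device biases, p̄/var_p the
    count-weighted mean and variance of the phase effects:

        E[t]     = μ + p̄
        Var(t)   = patient_sd² + ar_var + var_p,
                   ar_var = innovation_sd²/(1 − ar_coefficient²)
        bias     = b0 + b1·p̄                       (E[t·ε] = 0)
        between  = b1²·patient_sd² + test_patient_sd²
        within   = b1²·(ar_var + var_p) + test_noise_sd²
                   + ref_cv²·(Var(t) + E[t]²)
    """
    counts = config.phase_counts()
    total = sum(counts.values())
    weights = np.array([counts[p] / total for p in DEFAULT_PHASES])
    effects = np.array([config.phase_effects.get(p, 0.0) for p in DEFAULT_PHASES])
    p_bar = float(weights @ effects)
    var_p = float(weights @ (effects - p_bar) ** 2)

    ar_var = config.innovation_sd**2 / (1.0 - config.ar_coefficient**2)
    mean_t = config.patient_mean_ci + p_bar
    var_t = config.patient_sd**2 + ar_var + var_p

    bias = config.test_bias0 + config.test_bias1 * p_bar
    between = (config.test_bias1**2) * config.patient_sd**2 + config.test_patient_sd**2
    within = (
        (config.test_bias1**2) * (ar_var + var_p)
        + config.test_noise_sd**2
        + config.ref_cv**2 * (var_t + mean_t**2)
    )
    return ExpectedAgreement(bias=bias, sigma2_between=between, sigma2_within=within)


def simulate_cohort(
    config: SimulationConfig,
    *,
    device_name: str = "synthetic_device",
    reference_name: str = "thermodilution",
) -> CohortDataset:
    """Draw one cohort; identical (seed, config) gives a bit-identical dataset.

    The returned dataset carries ``ground_truth``: the config fields plus
    the :func:`expected_agreement` decomposition.
    """
    rng = np.random.default_rng(config.seed)
    phases = config.phase_sequence()
    m = len(phases)
    k = config.n_patients
    effects = np.array([config.phase_effects.get(p, 0.0) for p in phases])

    # Patient-level draws (k,), then within-patient series (k, m).
    T = config.patient_mean_ci + config.patient_sd * rng.standard_normal(k)
    u = config.test_patient_sd * rng.standard_normal(k)

    ar_sd = config.innovation_sd / np.sqrt(1.0 - config.ar_coefficient**2)
    a = np.empty((k, m))
    a[:, 0] = ar_sd * rng.standard_normal(k)
    innov = config.innovation_sd * rng.standard_normal((k, max(m - 1, 0)))
    for j in range(1, m):
        a[:, j] = config.ar_coefficient * a[:, j - 1] + innov[:, j - 1]

    t = np.maximum(_TRUE_FLOOR, T[:, None] + effects[None, :] + a)
    eps = config.ref_cv * rng.standard_normal((k, m))
    eta = config.test_noise_sd * rng.standard_normal((k, m))

    ci_ref = np.maximum(_OBS_FLOOR, t * (1.0 + eps))
    ci_test = np.maximum(
        _OBS_FLOOR,
        t
        + config.test_bias0
        + config.test_bias1 * (t - config.patient_mean_ci)
        + u[:, None]
        + eta,
    )

    frame = pd.DataFrame(
        {
            "patient_id": np.repeat([f"P{i + 1:03d}" for i in range(k)], m),
            "time_index": np.tile(np.arange(m), k),
            "phase": phases * k,
            "ci_ref": ci_ref.ravel(),
            "ci_test": ci_test.ravel(),
        }
    )
    exp = expected_agreement(config)
    truth = {
        "config": {
            **{f: getattr(config, f) for f in (
                "n_patients", "patient_mean_ci", "patient_sd", "ar_coefficient",
                "innovation_sd", "ref_cv", "test_bias0", "test_bias1",
                "test_patient_sd", "test_noise_sd", "seed")},
            "measurements_per_patient": config.phase_counts(),
            "phase_effects": dict(config.phase_effects),
        },
        "bias": exp.bias,
        "sigma2_between": exp.sigma2_between,
        "sigma2_within": exp.sigma2_within,
        "sd_total": exp.sd_total,
        "true_ci": t.ravel().tolist() if k * m <= 1000 else None,
    }
    return CohortDataset(
        frame=frame,
        device_name=device_name,
        reference_name=reference_name,
        ground_truth=truth,
    )
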