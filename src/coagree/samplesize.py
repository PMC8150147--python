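"""Sample-size calculations for method-comparison studies.

Two designs are covered:

* an equivalence design on paired differences, using the classic
  two-one-sided-tests (TOST) normal-approximation formula
  N = 2·(z₁₋α + z₁₋β/₂)²·σ² / (Δ − |δ|)², where σ is the SD of paired
  differences, Δ the equivalence margin and δ the assumed true mean
  difference; and

* Bland's precision-based size for the limits of agreement, requiring
  the 95% CI of a limit to have a chosen half-width w.  With
  SE(LOA) ≈ σ·√(3/N), solving 1.96·σ·√(3/N) ≈ w... the conventional
  shortcut N = 3·(z·σ/w)² treats w as the z-scaled half-width target;
  this is the form that the published post-hoc calculations use.

Both return the real-valued N and its nearest-integer rounding (the
published figures are nearest-integer, not ceilings).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.stats as st

__all__ = [
    "EquivalenceDesign",
    "LoaPrecisionDesign",
    "SampleSizeResult",
    "equivalence_n",
    "loa_precision_n",
    "tost_rejection_rate",
]


@dataclass(frozen=True)
class EquivalenceDesign:
    """Inputs of the TOST equivalence sample-size formula (units: L·min⁻¹·m⁻²)."""

    sd_diff: float
    margin: float
    true_diff: float = 0.0
    alpha: float = 0.05
    power: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.sd_diff <= 0:
            raise ValueError("sd_diff must be > 0")
        if self.margin <= abs(self.true_diff):
            raise ValueError(
                "equivalence margin must exceed |true_diff| (otherwise N is infinite)"
            )


@dataclass(frozen=True)
class LoaPrecisionDesign:
    """Inputs of Bland's precision-based size for a limit of agreement."""

    sd_diff: float
    ci_halfwidth: float
    z: float = 1.96

    def __post_init__(self) -> None:
        if self.sd_diff <= 0:
            raise ValueError("sd_diff must be > 0")
        if self.ci_halfwidth <= 0:
            raise ValueError("ci_halfwidth must be > 0")


@dataclass(frozen=True)
class SampleSizeResult:
    """Rounded and raw N plus the echoed design inputs and formula constants."""

    n: int
    n_raw: float
    method: str
    inputs: dict
    constants: dict


def equivalence_n(design: EquivalenceDesign) -> SampleSizeResult:
    """Measurements needed for a TOST equivalence design on paired differences.

    N = 2·(z₁₋α + z₁₋β/₂)²·sd² / (margin − |true_diff|)², nearest integer.
    The β/2 quantile is the TOST convention: each one-sided test must
    reject, splitting the type-II error across the two bounds.
    """
    beta = 1.0 - design.power
    z_a = st.norm.ppf(1.0 - design.alpha)
    z_b = st.norm.ppf(1.0 - beta / 2.0)
    delta = design.margin - abs(design.true_diff)
    n_raw = 2.0 * (z_a + z_b) ** 2 * design.sd_diff**2 / delta**2
    return SampleSizeResult(
        n=int(round(n_raw)),
        n_raw=float(n_raw),
        method="tost_equivalence",
        inputs=asdict(design),
        constants={"z_one_minus_alpha": float(z_a), "z_one_minus_beta_half": float(z_b)},
    )


def loa_precision_n(design: LoaPrecisionDesign) -> SampleSizeResult:
    """Measurements needed for a target LOA-CI half-width: N = 3·(z·sd/w)²."""
    n_raw = 3.0 * (design.z * design.sd_diff / design.ci_halfwidth) ** 2
    return SampleSizeResult(
        n=int(round(n_raw)),
        n_raw=float(n_raw),
        method="loa_precision",
        inputs=asdict(design),
        constants={"z": design.z, "se_loa_model": "sd*sqrt(3/N)"},
    )


def tost_rejection_rate(
    design: EquivalenceDesign,
    n: int,
    n_replicates: int = 2000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo TOST power at sample size ``n`` under the design.

    Each replicate draws n paired differences from
    Normal(true_diff, sd_diff²) and declares equivalence when the
    (1 − 2α) t-interval for the mean lies inside (−margin, margin) —
    equivalent to both one-sided α-level tests rejecting.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    x = design.true_diff + design.sd_diff * rng.standard_normal((n_replicates, n))
    means = x.mean(axis=1)
    sds = x.std(axis=1, ddof=1)
    tcrit = st.t.ppf(1.0 - design.alpha, n - 1)
    half = tcrit * sds / np.sqrt(n)
    reject = (means - half > -design.margin) & (means + half < design.margin)
    return float(reject.mean())
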