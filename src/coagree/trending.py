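"""Trending ability: consecutive-change pairs, four-quadrant concordance,
and the four-zone error grid.

A monitor can have acceptable average agreement yet track changes in
cardiac index poorly.  Trending is assessed on the percent changes of
two consecutive measurements of the same device: the four-quadrant (4Q)
plot scatters the test-device change against the reference change and
reports the concordance rate (same-direction fraction) after excluding
small changes, while the error grid classifies every change pair into
four clinical zones built from 5% / 15% magnitude bins:

  zone 1  both changed in the same direction to the same extent (or both
          below 5%, i.e. neither really changed) — uniform treatment
  zone 2  same direction, different extent — insufficient or exaggerated
          treatment
  zone 3  exactly one device registered a change — unnecessary treatment
          started, or necessary treatment withheld
  zone 4  opposite directions — opposite treatment
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .measurements import CohortDataset

__all__ = [
    "DeltaPair",
    "ErrorGridResult",
    "FourQuadrantResult",
    "delta_pairs",
    "magnitude_category",
    "classify_zone",
    "error_grid",
    "four_quadrant",
]


@dataclass(frozen=True)
class DeltaPair:
    """Percent (and absolute) change between consecutive measurements.

    Percent change is relative to the earlier measurement of the same
    device: 100·(CI_t − CI_{t−1})/CI_{t−1}.  ``phase`` is the phase of
    the later endpoint, used for phase-stratified trending.  Pairs never
    span two patients.
    """

    patient_id: str
    from_time: int
    to_time: int
    pct_ref: float
    pct_test: float
    abs_ref: float
    abs_test: float
    phase: str


@dataclass(frozen=True)
class ErrorGridResult:
    """Zone counts/percentages for a set of delta pairs.

    ``reported`` is False when n_deltas falls below ``min_n`` — mirrors
    suppressing the grid for phases with too few measurements.
    """

    n_deltas: int
    zone_counts: tuple[int, int, int, int]
    zone_percentages: tuple[float, float, float, float]
    reported: bool
    min_n: int


@dataclass(frozen=True)
class FourQuadrantResult:
    """Concordance of change direction after central exclusion.

    ``concordance_rate`` is the percentage of retained pairs whose
    changes share a sign; None (with ``defined`` False) if every pair
    fell inside the exclusion zone.
    """

    n_deltas: int
    n_excluded: int
    concordance_rate: float | None
    exclusion_threshold: float
    exclusion_mode: str
    defined: bool = True

    @property
    def n_retained(self) -> int:
        return self.n_deltas - self.n_excluded


def delta_pairs(dataset: CohortDataset) -> list[DeltaPair]:
    """Consecutive within-patient change pairs; a patient with m readings
    contributes m − 1 pairs, so a contiguous cohort yields N − k in total."""
    pairs: list[DeltaPair] = []
    for _, grp in dataset.frame.groupby("patient_id", sort=False):
        ref = grp["ci_ref"].to_numpy()
        test = grp["ci_test"].to_numpy()
        times = grp["time_index"].to_numpy()
        phases = grp["phase"].to_numpy()
        pid = grp["patient_id"].iloc[0]
        for j in range(1, len(grp)):
            pairs.append(
                DeltaPair(
                    patient_id=pid,
                    from_time=int(times[j - 1]),
                    to_time=int(times[j]),
                    pct_ref=100.0 * (ref[j] - ref[j - 1]) / ref[j - 1],
                    pct_test=100.0 * (test[j] - test[j - 1]) / test[j - 1],
                    abs_ref=float(ref[j] - ref[j - 1]),
                    abs_test=float(test[j] - test[j - 1]),
                    phase=phases[j],
                )
            )
    return pairs


def magnitude_category(pct: float) -> Literal["none", "moderate", "large"]:
    """Bin a percent change: <5% none, 5–15% (inclusive) moderate, >15% large."""
    if not np.isfinite(pct):
        raise ValueError("percent change must be finite")
    a = abs(pct)
    if a < 5.0:
        return "none"
    if a <= 15.0:
        return "moderate"
    return "large"


def classify_zone(pair: DeltaPair) -> int:
    """Error-grid zone (1–4) of one change pair.

    A sub-5% change counts as "no change": two no-changes are zone 1
    regardless of direction, exactly one no-change is zone 3, and among
    pairs where both devices changed, same direction with matching
    magnitude bin is zone 1, same direction with differing bin is
    zone 2, and opposite directions are zone 4.
    """
    cr = magnitude_category(pair.pct_ref)
    ct = magnitude_category(pair.pct_test)
    if cr == "none" and ct == "none":
        return 1
    if (cr == "none") != (ct == "none"):
        return 3
    same_sign = (pair.pct_ref > 0) == (pair.pct_test > 0)
    if not same_sign:
        return 4
    return 1 if cr == ct else 2


def error_grid(
    deltas: Sequence[DeltaPair], min_n: int = 30
) -> ErrorGridResult:
    """Classify every delta pair and tabulate zone counts and percentages.

    Results with fewer than ``min_n`` pairs are computed but flagged
    unreported, reproducing the convention of suppressing error grids
    for sparsely measured phases.
    """
    if len(deltas) == 0:
        raise ValueError("error grid needs at least one delta pair")
    counts = [0, 0, 0, 0]
    for p in deltas:
        counts[classify_zone(p) - 1] += 1
    n = len(deltas)
    pct = tuple(100.0 * c / n for c in counts)
    return ErrorGridResult(
        n_deltas=n,
        zone_counts=tuple(counts),
        zone_percentages=pct,
        reported=n >= min_n,
        min_n=min_n,
    )


def four_quadrant(
    deltas: Sequence[DeltaPair],
    exclusion: float = 10.0,
    mode: Literal["percent", "absolute"] = "percent",
) -> FourQuadrantResult:
    """Four-quadrant concordance with a central exclusion zone.

    A pair is excluded when both devices' changes are small: below
    ``exclusion`` percent (percent mode) or below ``exclusion``
    L·min⁻¹·m⁻² in absolute change (absolute mode).  Concordance is the
    percentage of retained pairs with sign(Δref) = sign(Δtest); an
    exactly-zero change is concordant only with another zero.
    """
    if len(deltas) == 0:
        raise ValueError("four-quadrant analysis needs at least one delta pair")
    if mode == "percent":
        a = np.array([abs(p.pct_ref) for p in deltas])
        b = np.array([abs(p.pct_test) for p in deltas])
    elif mode == "absolute":
        a = np.array([abs(p.abs_ref) for p in deltas])
        b = np.array([abs(p.abs_test) for p in deltas])
    else:
        raise ValueError(f"unknown exclusion mode {mode!r}")
    excluded = (a < exclusion) & (b < exclusion)
    retained = [p for p, e in zip(deltas, excluded) if not e]
    if not retained:
        return FourQuadrantResult(
            n_deltas=len(deltas),
            n_excluded=int(excluded.sum()),
            concordance_rate=None,
            exclusion_threshold=exclusion,
            exclusion_mode=mode,
            defined=False,
        )
    conc = sum(
        1 for p in retained if np.sign(p.pct_ref) == np.sign(p.pct_test)
    )
    return FourQuadrantResult(
        n_deltas=len(deltas),
        n_excluded=int(excluded.sum()),
        concordance_rate=100.0 * conc / len(retained),
        exclusion_threshold=exclusion,
        exclusion_mode=mode,
        defined=True,
    )
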