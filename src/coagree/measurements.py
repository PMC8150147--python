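"""Data model, validation and CSV I/O for paired cardiac-index series.

A cohort is a set of patients, each with a time-ordered series of
simultaneous cardiac-index (CI) readings from a reference method
(bolus thermodilution via pulmonary artery catheter) and one test
device (e.g. a bioreactance or pulse-contour monitor).  All values are
in L·min⁻¹·m⁻².  The canonical on-disk form is a tidy-wide CSV: one
row per timepoint carrying both devices' readings, because every
downstream statistic is pairwise by construction.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Clinical phases of an off-pump coronary bypass series, in protocol order:
#: pre-induction baseline, aortic side-clamping (proximal anastomoses),
#: distal coronary anastomoses (heart verticalized), ICU pre-extubation,
#: plus a catch-all for measurements outside the named phases.
DEFAULT_PHASES: tuple[str, ...] = (
    "baseline",
    "aortic_side_clamp",
    "distal_anastomoses",
    "icu_pre_extubation",
    "other",
)

#: Canonical column names of the tidy-wide CSV layout.
COLUMNS: tuple[str, ...] = ("patient_id", "time_index", "phase", "ci_ref", "ci_test")


class SchemaError(ValueError):
    """A required column could not be resolved in the input file."""


class CohortValidationError(ValueError):
    """A dataset row violates a structural invariant (cites the row)."""


@dataclass(frozen=True)
class PairedMeasurement:
    """One simultaneous reference/test CI observation within a patient series."""

    patient_id: str
    time_index: int
    phase: str
    ci_ref: float
    ci_test: float


@dataclass
class CohortDataset:
    """Validated collection of paired CI measurements.

    ``frame`` holds one row per measurement with columns
    ``patient_id, time_index, phase, ci_ref, ci_test``, sorted by
    (patient, time).  ``phase_labels`` is the set of labels considered
    known for phase filtering; labels present in the data are always
    included.  ``ground_truth`` is populated by the synthetic generator
    and carries the parameters the data were drawn from.
    """

    frame: pd.DataFrame
    device_name: str = "test"
    reference_name: str = "reference"
    phase_labels: tuple[str, ...] = DEFAULT_PHASES
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.loc[:, list(COLUMNS)].copy()
        df["time_index"] = df["time_index"].astype(np.int64)
        df["ci_ref"] = df["ci_ref"].astype(float)
        df["ci_test"] = df["ci_test"].astype(float)
        df["patient_id"] = df["patient_id"].astype(str)
        df["phase"] = df["phase"].astype(str)
        _validate_rows(df)
        df = df.sort_values(["patient_id", "time_index"], kind="stable")
        df = df.reset_index(drop=True)
        self.frame = df
        observed = tuple(x for x in df["phase"].unique() if x not in self.phase_labels)
        self.phase_labels = tuple(self.phase_labels) + observed

    # -- basic accessors -------------------------------------------------

    @property
    def n_measurements(self) -> int:
        return len(self.frame)

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.frame["patient_id"]))

    def __len__(self) -> int:
        return len(self.frame)

    def iter_measurements(self) -> Iterator[PairedMeasurement]:
        for row in self.frame.itertuples(index=False):
            yield PairedMeasurement(
                patient_id=row.patient_id,
                time_index=int(row.time_index),
                phase=row.phase,
                ci_ref=float(row.ci_ref),
                ci_test=float(row.ci_test),
            )

    def filter_phase(self, phase: str) -> "CohortDataset":
        return filter_phase(self, phase)


def _validate_rows(df: pd.DataFrame) -> None:
    """Raise CohortValidationError citing the offending row (0-based)."""
    if len(df) == 0:
        return
    bad = df.index[(df["ci_ref"] <= 0) | ~np.isfinite(df["ci_ref"])]
    if len(bad):
        raise CohortValidationError(
            f"non-positive or non-finite ci_ref at row {bad[0]}"
        )
    bad = df.index[(df["ci_test"] <= 0) | ~np.isfinite(df["ci_test"])]
    if len(bad):
        raise CohortValidationError(
            f"non-positive or non-finite ci_test at row {bad[0]}"
        )
    bad = df.index[df["time_index"] < 0]
    if len(bad):
        raise CohortValidationError(f"negative time_index at row {bad[0]}")
    dup = df.duplicated(subset=["patient_id", "time_index"], keep="first")
    if dup.any():
        raise CohortValidationError(
            f"duplicate (patient_id, time_index) at row {df.index[dup][0]}"
        )


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    device_name: str = "test",
    reference_name: str = "reference",
    phase_labels: tuple[str, ...] = DEFAULT_PHASES,
) -> CohortDataset:
    """Read a tidy-wide cohort CSV into a validated :class:`CohortDataset`.

    ``schema`` maps canonical names (``patient_id`` .. ``ci_test``) to the
    column names actually present in the file; canonical names are used
    where a mapping entry is absent.
    """
    schema = dict(schema or {})
    raw = pd.read_csv(
        path,
        dtype={schema.get("patient_id", "patient_id"): str},
        float_precision="round_trip",
    )
    rename = {}
    for canonical in COLUMNS:
        source = schema.get(canonical, canonical)
        if source not in raw.columns:
            raise SchemaError(
                f"column {source!r} (for {canonical!r}) not found in {path}; "
                f"available: {', '.join(raw.columns)}"
            )
        rename[source] = canonical
    frame = raw.rename(columns=rename)
    return CohortDataset(
        frame=frame,
        device_name=device_name,
        reference_name=reference_name,
        phase_labels=phase_labels,
    )


def write_cohort(dataset: CohortDataset, path) -> None:
    """Write the cohort as UTF-8 CSV at full float precision (round-trip safe)."""
    dataset.frame.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def filter_phase(dataset: CohortDataset, phase: str) -> CohortDataset:
    """Subset to one clinical phase; patients without matching rows drop out.

    A known label absent from the data yields an empty dataset; an unknown
    label is an error listing the known labels.
    """
    if phase not in dataset.phase_labels:
        raise ValueError(
            f"unknown phase {phase!r}; known phases: "
            f"{', '.join(dataset.phase_labels)}"
        )
    sub = dataset.frame[dataset.frame["phase"] == phase]
    return replace(dataset, frame=sub.reset_index(drop=True), ground_truth=None)


def long_to_wide(
    frame: pd.DataFrame,
    *,
    reference_label: str,
    device_label: str,
    patient_col: str = "patient_id",
    time_col: str = "time_index",
    phase_col: str = "phase",
    method_col: str = "method",
    value_col: str = "ci",
) -> pd.DataFrame:
    """Convert a long table (one row per device reading) to tidy-wide layout.

    Rows are matched on (patient, time); both devices must be present at
    every retained timepoint.
    """
    wide = frame.pivot_table(
        index=[patient_col, time_col, phase_col],
        columns=method_col,
        values=value_col,
        aggfunc="first",
    ).reset_index()
    for label in (reference_label, device_label):
        if label not in wide.columns:
            raise SchemaError(f"method label {label!r} not present in {method_col!r}")
    wide = wide.dropna(subset=[reference_label, device_label])
    out = wide.rename(
        columns={
            patient_col: "patient_id",
            time_col: "time_index",
            phase_col: "phase",
            reference_label: "ci_ref",
            device_label: "ci_test",
        }
    )
    out = out.loc[:, list(COLUMNS)]
    out.columns.name = None
    return out.reset_index(drop=True)
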