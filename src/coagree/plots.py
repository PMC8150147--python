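"""Bland–Altman and four-quadrant figures (headless-safe)."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .agreement import AgreementResult, differences
from .measurements import CohortDataset
from .trending import DeltaPair, FourQuadrantResult

__all__ = ["plot_bland_altman", "plot_trending"]


def plot_bland_altman(
    dataset: CohortDataset, result: AgreementResult, path
) -> None:
    """Difference-vs-mean scatter with bias, LOA and LOA-CI lines.

    Lines are drawn exactly at the values carried by ``result``, so the
    figure cannot drift from the tabulated statistics.
    """
    dm = differences(dataset)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(dm["mean"], dm["diff"], s=12, alpha=0.6, edgecolors="none")
    ax.axhline(result.bias, color="k", lw=1.2, label=f"bias {result.bias:.2f}")
    for y, lab in ((result.loa_lower, "lower LOA"), (result.loa_upper, "upper LOA")):
        ax.axhline(y, color="k", ls="--", lw=1.0, label=f"{lab} {y:.2f}")
    for ci in (result.loa_lower_ci, result.loa_upper_ci):
        if ci is not None:
            for y in ci:
                ax.axhline(y, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("mean CI of the two methods (L·min⁻¹·m⁻²)")
    ax.set_ylabel(f"{dataset.device_name} − {dataset.reference_name} (L·min⁻¹·m⁻²)")
    ax.set_title(f"Bland–Altman: {dataset.device_name} vs {dataset.reference_name}")
    ax.legend(fontsize=8, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trending(
    deltas: Sequence[DeltaPair], result: FourQuadrantResult, path
) -> None:
    """4Q scatter of ΔCI_test vs ΔCI_ref with identity line and exclusion box."""
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    if deltas:
        xs = [p.pct_ref for p in deltas]
        ys = [p.pct_test for p in deltas]
        ax.scatter(xs, ys, s=12, alpha=0.6, edgecolors="none")
        lim = max(20.0, max(abs(v) for v in xs + ys) * 1.05)
    else:
        lim = 20.0
    ax.plot([-lim, lim], [-lim, lim], color="k", lw=0.8)  # identity through origin
    if result.exclusion_mode == "percent" and result.exclusion_threshold > 0:
        e = result.exclusion_threshold
        ax.add_patch(
            plt.Rectangle((-e, -e), 2 * e, 2 * e, fill=False,
                          edgecolor="red", ls="--", lw=1.0)
        )
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    if result.defined and result.concordance_rate is not None:
        note = (f"concordance {result.concordance_rate:.1f}% "
                f"({result.n_retained}/{result.n_deltas} retained)")
    else:
        note = "all pairs inside exclusion zone"
    ax.annotate(note, xy=(0.02, 0.98), xycoords="axes fraction", va="top", fontsize=8)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("Δ reference CI (%)")
    ax.set_ylabel("Δ test CI (%)")
    ax.set_title("Four-quadrant trending plot")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
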