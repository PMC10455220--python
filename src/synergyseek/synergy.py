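"""Bliss-independence scoring of dose-response combination matrices.

For each combination cell the observed inhibition is compared with the Bliss
expectation from the two single agents at the same doses,
``y_a + y_b - y_a*y_b``; the excess over the expectation, on the x100
percent scale, averaged over the whole grid is the Bliss score.  A positive
average marks synergy, negative antagonism, exactly zero additivity.
Inhibition is clamped to [0, 1] before the expectation, so growth
stimulation above the untreated control counts as zero inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DoseResponseMatrix

__all__ = [
    "SynergyResult",
    "ClassSynergySummary",
    "percent_inhibition",
    "bliss_expected",
    "bliss_matrix_score",
    "aggregate_class_synergy",
    "plot_excess_contour",
]


@dataclass
class SynergyResult:
    drug_a: str
    drug_b: str
    excess: np.ndarray  # percent scale, over the non-control grid
    bliss_score: float
    label: str

    @staticmethod
    def label_for(score: float) -> str:
        if score > 0:
            return "synergistic"
        if score < 0:
            return "antagonistic"
        return "additive"


@dataclass
class ClassSynergySummary:
    cell_line: str
    inhibitor_class: str
    mean_bliss: float
    n_combinations: int
    label: str


def percent_inhibition(viability_pct) -> np.ndarray | float:
    """Fractional inhibition from percent viability, clamped to [0, 1]."""
    v = np.asarray(viability_pct, dtype=float)
    y = np.clip(1.0 - v / 100.0, 0.0, 1.0)
    return float(y) if np.isscalar(viability_pct) or v.ndim == 0 else y


def bliss_expected(y_a, y_b):
    """Bliss-independence expected inhibition of the combination."""
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    if np.any((y_a < 0) | (y_a > 1)) or np.any((y_b < 0) | (y_b > 1)):
        raise ValueError("inhibition inputs must lie in [0, 1]")
    out = y_a + y_b - y_a * y_b
    return float(out) if out.ndim == 0 else out


def bliss_matrix_score(m: DoseResponseMatrix) -> SynergyResult:
    """Average Bliss excess (percent scale) over the combination grid.

    For each cell (i > 0, j > 0): excess = [observed inhibition -
    expected(mono_a(i), mono_b(j))] * 100.  The Bliss score is the
    arithmetic mean of the excess matrix; its sign sets the label.
    """
    if len(m.conc_a) < 2 or len(m.conc_b) < 2:
        raise ValueError("dose matrix needs at least one non-control cell")
    y = percent_inhibition(m.viability)
    mono_a = y[1:, 0]
    mono_b = y[0, 1:]
    expected = bliss_expected(mono_a[:, None], mono_b[None, :])
    excess = (y[1:, 1:] - expected) * 100.0
    score = float(excess.mean())
    return SynergyResult(
        drug_a=m.drug_a,
        drug_b=m.drug_b,
        excess=excess,
        bliss_score=score,
        label=SynergyResult.label_for(score),
    )


def aggregate_class_synergy(records) -> tuple[list[ClassSynergySummary], pd.DataFrame]:
    """Aggregate (cell line, class, bliss score) records the ALMANAC way.

    Returns the per-(cell line, class) mean scores with labels, and a
    per-class table counting cell lines whose mean is synergistic (> 0) or
    antagonistic (< 0).
    """
    records = list(records)
    if not records:
        raise ValueError("no synergy records to aggregate")
    df = pd.DataFrame(records, columns=["cell_line", "inhibitor_class", "bliss_score"])
    summaries = []
    for (cl, cls), grp in df.groupby(["cell_line", "inhibitor_class"], sort=True):
        mean = float(grp["bliss_score"].mean())
        summaries.append(
            ClassSynergySummary(
                cell_line=cl,
                inhibitor_class=cls,
                mean_bliss=mean,
                n_combinations=len(grp),
                label=SynergyResult.label_for(mean),
            )
        )
    rows = []
    per_class: dict[str, dict[str, int]] = {}
    for s in summaries:
        d = per_class.setdefault(s.inhibitor_class, {"synergistic": 0, "antagonistic": 0, "additive": 0})
        d[s.label] += 1
    for cls in sorted(per_class):
        d = per_class[cls]
        rows.append((cls, d["synergistic"], d["antagonistic"], d["additive"]))
    counts = pd.DataFrame(
        rows, columns=["inhibitor_class", "n_synergistic", "n_antagonistic", "n_additive"]
    )
    return summaries, counts


def plot_excess_contour(m: DoseResponseMatrix, result: SynergyResult, path) -> None:
    """Contour plot of the Bliss excess over the combination dose grid (SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    vmax = max(abs(result.excess).max(), 1e-6)
    im = ax.contourf(
        np.arange(len(m.conc_b) - 1), np.arange(len(m.conc_a) - 1), result.excess,
        levels=12, cmap="RdBu_r", vmin=-vmax, vmax=vmax,
    )
    ax.set_xticks(np.arange(len(m.conc_b) - 1), [f"{c:g}" for c in m.conc_b[1:]])
    ax.set_yticks(np.arange(len(m.conc_a) - 1), [f"{c:g}" for c in m.conc_a[1:]])
    ax.set_xlabel(f"{m.drug_b} (uM)")
    ax.set_ylabel(f"{m.drug_a} (uM)")
    ax.set_title(f"Bliss excess (avg {result.bliss_score:.1f}, {result.label})")
    fig.colorbar(im, ax=ax, label="excess inhibition (%)")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
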