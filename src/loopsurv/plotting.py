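"""Survival-curve plots (log-scaled surviving fraction vs dose)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data import SurvivalDataset
from .model import ModelParameters, analytic_mean_survival

__all__ = ["plot_survival_curves"]


def plot_survival_curves(
    dataset: SurvivalDataset | None = None,
    curves: dict[str, tuple[ModelParameters, float]] | None = None,
    max_dose: float = 10.0,
    path: str | Path | None = None,
    title: str | None = None,
):
    """Plot measured points and/or model curves on a log survival axis.

    ``curves`` maps a legend label to (parameters, rsf); the curve is the
    closed-form mean survival. Writes to ``path`` if given, else returns the
    matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    if dataset is not None:
        for (line, o2, imp), grp in dataset.data.groupby(
            ["cell_line", "o2_percent", "impairment_label"]
        ):
            label = f"{line} {o2:g}% O2" + ("" if imp == "none" else f" {imp}")
            err = grp["sf_sem"] if grp["sf_sem"].notna().all() else None
            ax.errorbar(grp["dose_Gy"], grp["surviving_fraction"], yerr=err,
                        fmt="o", ms=4, capsize=2, label=label)
    if curves:
        doses = np.linspace(0.0, max_dose, 200)
        for label, (params, rsf) in curves.items():
            ax.plot(doses, analytic_mean_survival(params, doses, rsf), label=label)
    ax.set_yscale("log")
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("surviving fraction")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)
    return fig
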