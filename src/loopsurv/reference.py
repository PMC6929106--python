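"""Published fitted parameter panel used for demos, benchmarks and checks.

Fitted giant-loop model parameters reported in the experimental radiobiology
literature for a panel of cell lines: five tumor lines (human lung
adenocarcinoma/large-cell lines A549, H460, H1437; murine melanoma B16F10;
murine renal carcinoma Renca) measured at normoxia, 1% and 0.5% O2; CHO
wild-type with two DNA-PK-response-deficient mutants (V3: DNA-PKcs-deficient,
xrs5: Ku80-deficient) at normoxia and <1% O2; and H460/H1437 treated with an
ATM inhibitor at 100/200/500 nM. Lethality values are probabilities; HRF and
RSF are dimensionless factors.

These values serve as realistic ground-truth ranges for synthetic campaigns
and as fixed inputs to the oxygen-parameterization consistency check; the
package does not refit them.
"""

from __future__ import annotations

import pandas as pd

from .model import ModelParameters

__all__ = [
    "HYPOXIA_PANEL",
    "DNAPK_PANEL",
    "ATMI_PANEL",
    "hrf_panel",
    "lethality_parameters",
    "all_parameter_sets",
]

# Five-line hypoxia panel: lethality parameters (+/- 1 sigma) and fitted HRF
# at 1% and 0.5% O2.
HYPOXIA_PANEL = pd.DataFrame(
    [
        ("A549",   4.83e-3, 0.88e-3, 1.69e-1, 0.31e-1, 1.60, 2.04),
        ("H460",   3.28e-3, 1.20e-3, 2.41e-1, 0.86e-1, 1.24, 1.44),
        ("H1437",  3.83e-3, 0.83e-3, 1.37e-1, 0.38e-1, 1.09, 1.33),
        ("B16F10", 4.05e-3, 0.44e-3, 1.34e-1, 0.18e-1, 1.29, 1.44),
        ("Renca",  1.67e-3, 0.18e-3, 2.04e-1, 0.06e-1, 1.28, 1.67),
    ],
    columns=[
        "cell_line", "k_idsb", "k_idsb_err", "k_cdsb", "k_cdsb_err",
        "hrf_1pct", "hrf_0p5pct",
    ],
)

# CHO wild type with DNA-PK-response-deficient mutants; hypoxia label "<1%".
DNAPK_PANEL = pd.DataFrame(
    [
        ("CHO-WT", 4.38e-3, 1.37e-3, 2.33e-1, 0.27e-1, 2.44, 9.60, 0.19, 14.85, 0.50),
    ],
    columns=[
        "cell_line", "k_idsb", "k_idsb_err", "k_cdsb", "k_cdsb_err", "hrf",
        "rsf_v3", "rsf_v3_err", "rsf_xrs5", "rsf_xrs5_err",
    ],
)

# ATM-inhibitor panel: RSF per drug concentration, HRF at 1% O2.
ATMI_PANEL = pd.DataFrame(
    [
        ("H460",  3.88e-3, 2.19e-3, 2.55e-1, 0.85e-1, 1.31,
         1.73, 0.15, 2.56, 0.27, 4.21, 0.59),
        ("H1437", 3.11e-3, 0.86e-3, 1.50e-1, 0.35e-1, 1.10,
         1.77, 0.12, 2.52, 0.13, 3.77, 0.15),
    ],
    columns=[
        "cell_line", "k_idsb", "k_idsb_err", "k_cdsb", "k_cdsb_err", "hrf",
        "rsf_100nM", "rsf_100nM_err", "rsf_200nM", "rsf_200nM_err",
        "rsf_500nM", "rsf_500nM_err",
    ],
)


def hrf_panel(o2_percent: float) -> dict[str, float]:
    """Fitted HRF values of the five-line hypoxia panel at 1% or 0.5% O2."""
    if o2_percent == 1.0:
        col = "hrf_1pct"
    elif o2_percent == 0.5:
        col = "hrf_0p5pct"
    else:
        raise ValueError(f"panel HRF values exist for 1% and 0.5% O2 only, got {o2_percent}")
    return dict(zip(HYPOXIA_PANEL["cell_line"], HYPOXIA_PANEL[col]))


def lethality_parameters(cell_line: str) -> ModelParameters:
    """Model parameters (default constants + panel lethalities) for one line."""
    for panel in (HYPOXIA_PANEL, DNAPK_PANEL, ATMI_PANEL):
        row = panel[panel["cell_line"] == cell_line]
        if len(row):
            return ModelParameters(
                k_idsb=float(row["k_idsb"].iloc[0]),
                k_cdsb=float(row["k_cdsb"].iloc[0]),
            )
    raise KeyError(f"unknown cell line {cell_line!r}")


def all_parameter_sets() -> list[tuple[str, ModelParameters, float]]:
    """Every (label, parameters, rsf) combination in the panel.

    Includes the rsf = 1 baseline of every line plus each mutant/drug RSF,
    for use in parameter sweeps.
    """
    sets: list[tuple[str, ModelParameters, float]] = []
    for line in HYPOXIA_PANEL["cell_line"]:
        sets.append((line, lethality_parameters(line), 1.0))
    cho = lethality_parameters("CHO-WT")
    sets.append(("CHO-WT", cho, 1.0))
    sets.append(("CHO-V3", cho, float(DNAPK_PANEL["rsf_v3"].iloc[0])))
    sets.append(("CHO-xrs5", cho, float(DNAPK_PANEL["rsf_xrs5"].iloc[0])))
    for _, row in ATMI_PANEL.iterrows():
        params = ModelParameters(k_idsb=row["k_idsb"], k_cdsb=row["k_cdsb"])
        for conc in (100, 200, 500):
            sets.append((f"{row['cell_line']}+ATMi-{conc}nM", params, float(row[f"rsf_{conc}nM"])))
    return sets
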