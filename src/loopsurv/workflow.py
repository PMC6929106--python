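"""Staged fitting workflow and the oxygen-parameterization consistency check."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .conditions import HrfParameterization, hrf_from_oxygen
from .data import UNTREATED_LABEL, SurvivalDataset
from .fitting import FitResult, fit_hrf, fit_lethality, fit_rsf, predict_combined
from .model import ModelParameters

__all__ = ["ThreeStageFit", "three_stage_fit", "HrfDeviationReport", "hrf_deviation_report"]


@dataclass
class ThreeStageFit:
    """Results of the staged protocol for one cell line.

    ``lethality`` holds the normoxic (k_idsb, k_cdsb) fit; ``hrf`` maps
    o2_percent -> FitResult, ``rsf`` maps impairment label -> FitResult.
    """

    cell_line: str
    params: ModelParameters
    lethality: FitResult
    hrf: dict[float, FitResult] = field(default_factory=dict)
    rsf: dict[str, FitResult] = field(default_factory=dict)

    def predict(self, doses, o2_percent: float | None = None,
                impairment_label: str | None = None) -> np.ndarray:
        """Survival prediction for any fitted combination of conditions."""
        hrf = self.hrf[o2_percent].estimates["hrf"] if o2_percent is not None else 1.0
        rsf = self.rsf[impairment_label].estimates["rsf"] if impairment_label else 1.0
        return predict_combined(self.params, hrf, rsf, doses)


def three_stage_fit(
    dataset: SurvivalDataset,
    cell_line: str,
    params: ModelParameters | None = None,
    weighted: bool = False,
    n_starts: int = 5,
    random_state: int = 0,
) -> ThreeStageFit:
    """Run the full protocol for one cell line.

    1. Fit (k_idsb, k_cdsb) to the normoxic untreated records.
    2. With lethalities frozen, fit one HRF per hypoxic oxygen level from the
       untreated hypoxic records.
    3. With lethalities frozen, fit one RSF per impairment label from the
       normoxic impaired records.

    Combined hypoxia + impairment records are never fitted; they are covered
    by the zero-free-parameter prediction of :meth:`ThreeStageFit.predict`.
    """
    base = params or ModelParameters()
    normoxic = dataset.subset(cell_line=cell_line, impairment_label=UNTREATED_LABEL,
                              normoxic=True)
    if len(normoxic) == 0:
        raise ValueError(f"no normoxic untreated records for cell line {cell_line!r}")
    leth = fit_lethality(normoxic, base, weighted=weighted, n_starts=n_starts,
                         random_state=random_state)
    fitted = base.with_lethality(leth.estimates["k_idsb"], leth.estimates["k_cdsb"])
    out = ThreeStageFit(cell_line=cell_line, params=fitted, lethality=leth)

    hypoxic = dataset.subset(cell_line=cell_line, impairment_label=UNTREATED_LABEL,
                             normoxic=False)
    for o2 in sorted(hypoxic.data["o2_percent"].unique(), reverse=True):
        out.hrf[float(o2)] = fit_hrf(hypoxic.subset(o2_percent=float(o2)), fitted,
                                     weighted=weighted, k_cov=leth.covariance)

    impaired = dataset.subset(cell_line=cell_line, normoxic=True)
    labels = [l for l in impaired.data["impairment_label"].unique() if l != UNTREATED_LABEL]
    for label in sorted(labels):
        out.rsf[label] = fit_rsf(impaired.subset(impairment_label=label), fitted,
                                 weighted=weighted, k_cov=leth.covariance)
    return out


@dataclass(frozen=True)
class HrfDeviationReport:
    """Comparison of fitted HRF values against the oxygen parameterization."""

    o2_percent: float
    n_values: int
    mean_hrf: float
    parameterized_hrf: float
    abs_deviation: float
    abs_deviation_rounded: float

    def __str__(self) -> str:
        return (
            f"[O2] = {self.o2_percent}%: mean fitted HRF = {self.mean_hrf:.4f} "
            f"over {self.n_values} line(s); parameterization gives "
            f"{self.parameterized_hrf:.4f}; |deviation| = {self.abs_deviation:.4f} "
            f"(rounded: {self.abs_deviation_rounded:.2f})"
        )


def hrf_deviation_report(
    hrf_values: Mapping[str, float] | Iterable[float],
    par: HrfParameterization | None = None,
    o2_percent: float = 1.0,
) -> HrfDeviationReport:
    """How far the mean of fitted HRF values sits from the parameterization.

    ``hrf_values`` is a mapping cell line -> fitted HRF (or a plain sequence
    of HRFs) at one oxygen level. Returns the arithmetic mean, the
    parameterization value at that level, and their absolute difference both
    raw and rounded to two decimals (the reporting precision of the fitted
    values).
    """
    par = par or HrfParameterization()
    values = list(hrf_values.values()) if isinstance(hrf_values, Mapping) else list(hrf_values)
    if not values:
        raise ValueError("at least one fitted HRF value is required")
    mean = float(np.mean(values))
    pred = hrf_from_oxygen(par, o2_percent)
    dev = abs(mean - pred)
    return HrfDeviationReport(
        o2_percent=o2_percent,
        n_values=len(values),
        mean_hrf=mean,
        parameterized_hrf=pred,
        abs_deviation=dev,
        abs_deviation_rounded=round(dev, 2),
    )
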