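"""Ground-truth-known synthetic clonogenic survival datasets.

Emulates the experimental design the model is fitted to: a dose series of
1/2/4/8 Gy photons per condition, conditions spanning normoxia, one or two
hypoxia levels, and repair impairment (mutant or inhibitor concentration),
with multiplicative log-normal measurement noise on the surviving fraction.
Assays are triplicate by default (the usual clonogenic practice); every
replicate measurement is emitted as its own record so that fits retain the
full residual degrees of freedom, and mean +/- SEM aggregation is available
(``aggregate=True``) for display.

What the generator does NOT emulate: colony counting and plating-efficiency
statistics, cell-cycle structure, dose-rate effects, or any systematic
(non-multiplicative) error — parameter-recovery results on this data
demonstrate identifiability of the model under its own error assumptions,
not robustness to model misspecification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditions import OxygenCondition, RepairImpairment, condition_adjusted_params
from .data import UNTREATED_LABEL, SurvivalDataset
from .model import ModelParameters, analytic_mean_survival

__all__ = ["ConditionSpec", "GeneratorSpec", "CampaignTruth", "generate_dataset", "benchmark_campaign"]

DEFAULT_DOSES = (1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: oxygenation + repair impairment."""

    cell_line: str
    o2_percent: float = 20.0
    hrf: float = 1.0
    rsf: float = 1.0
    impairment_label: str = UNTREATED_LABEL
    drug_conc_nM: float = float("nan")


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic survival dataset.

    ``noise_sigma_log`` is the standard deviation of the additive Gaussian
    noise on ln(SF) per replicate (0 gives the exact model curves).
    ``aggregate=False`` (default) emits one record per replicate;
    ``aggregate=True`` emits the replicate mean with its standard error.
    Identical seeds give identical datasets.
    """

    true_params: ModelParameters
    conditions: tuple[ConditionSpec, ...]
    doses: tuple[float, ...] = DEFAULT_DOSES
    noise_sigma_log: float = 0.1
    n_replicates: int = 3
    seed: int = 0
    aggregate: bool = False

    def __post_init__(self) -> None:
        if self.noise_sigma_log < 0:
            raise ValueError("noise_sigma_log must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")


def _true_curve(params: ModelParameters, cond: ConditionSpec, doses: np.ndarray) -> np.ndarray:
    oxy = OxygenCondition.fitted(cond.hrf) if cond.hrf != 1.0 else OxygenCondition()
    imp = RepairImpairment(cond.impairment_label, cond.rsf) if cond.rsf != 1.0 \
        else RepairImpairment()
    adj, rsf = condition_adjusted_params(params, oxy, imp)
    return np.asarray(analytic_mean_survival(adj, doses, rsf))


def generate_dataset(spec: GeneratorSpec) -> SurvivalDataset:
    """Generate a survival dataset from a ground-truth parameter set.

    For every condition, dose and replicate the surviving fraction is the
    closed-form model value times ``exp(eps)`` with
    ``eps ~ N(0, noise_sigma_log^2)``, truncated at 1. With
    ``aggregate=True`` each (condition, dose) record instead stores the
    replicate mean and, for more than one replicate, the standard error of
    that mean.
    """
    rng = np.random.default_rng(spec.seed)
    doses = np.asarray(spec.doses, dtype=float)
    rows = []
    for cond in spec.conditions:
        truth = _true_curve(spec.true_params, cond, doses)
        for dose, sf_true in zip(doses, truth):
            if spec.noise_sigma_log > 0:
                eps = rng.normal(0.0, spec.noise_sigma_log, size=spec.n_replicates)
                reps = np.minimum(sf_true * np.exp(eps), 1.0)
            else:
                reps = np.full(spec.n_replicates, sf_true)
            base = {
                "cell_line": cond.cell_line,
                "o2_percent": cond.o2_percent,
                "impairment_label": cond.impairment_label,
                "drug_conc_nM": cond.drug_conc_nM,
                "dose_Gy": float(dose),
            }
            if spec.aggregate:
                sem = float(reps.std(ddof=1) / np.sqrt(spec.n_replicates)) \
                    if spec.n_replicates > 1 else np.nan
                rows.append({**base, "surviving_fraction": float(reps.mean()),
                             "sf_sem": sem})
            else:
                for r, sf in enumerate(reps, start=1):
                    rows.append({**base, "replicate": r,
                                 "surviving_fraction": float(sf), "sf_sem": np.nan})
    return SurvivalDataset(pd.DataFrame(rows))


@dataclass
class CampaignTruth:
    """A generated multi-line campaign bundled with its ground truth.

    ``lethality`` maps cell line -> (k_idsb, k_cdsb); ``hrf`` maps
    (cell_line, o2_percent) -> HRF; ``rsf`` maps
    (cell_line, impairment_label) -> RSF.
    """

    dataset: SurvivalDataset
    lethality: dict[str, tuple[float, float]] = field(default_factory=dict)
    hrf: dict[tuple[str, float], float] = field(default_factory=dict)
    rsf: dict[tuple[str, str], float] = field(default_factory=dict)


def benchmark_campaign(
    seed: int = 0,
    noise_sigma_log: float = 0.1,
    n_replicates: int = 3,
    doses: tuple[float, ...] = DEFAULT_DOSES,
    aggregate: bool = False,
) -> CampaignTruth:
    """Full multi-cell-line campaign with realistic ground-truth ranges.

    Mirrors the shape of the model's published benchmark panels: five tumor
    lines at normoxia/1%/0.5% O2; one wild type with two repair-deficient
    mutants under normoxia and hypoxia; and two lines crossed with three
    inhibitor concentrations under normoxia and hypoxia (including the
    combined hypoxia + drug conditions used for prediction checks).
    Ground-truth parameters are drawn within the published ranges:
    k_idsb in [1.5, 5]e-3, k_cdsb in [0.13, 0.26], HRF in [1.1, 2.5],
    RSF in [1.7, 15].
    """
    rng = np.random.default_rng(seed)
    truth = CampaignTruth(dataset=None)  # dataset attached at the end
    conditions: list[ConditionSpec] = []
    lethality: dict[str, tuple[float, float]] = {}

    def draw_ks() -> tuple[float, float]:
        return float(rng.uniform(1.5e-3, 5e-3)), float(rng.uniform(0.13, 0.26))

    # five-line hypoxia panel: normoxia + 1% + 0.5% O2
    for line in ("SYN-A", "SYN-B", "SYN-C", "SYN-D", "SYN-E"):
        lethality[line] = draw_ks()
        hrf_1 = float(rng.uniform(1.1, 1.7))
        hrf_05 = float(min(hrf_1 + rng.uniform(0.1, 0.8), 2.5))
        conditions.append(ConditionSpec(line))
        conditions.append(ConditionSpec(line, o2_percent=1.0, hrf=hrf_1))
        conditions.append(ConditionSpec(line, o2_percent=0.5, hrf=hrf_05))
        truth.hrf[(line, 1.0)] = hrf_1
        truth.hrf[(line, 0.5)] = hrf_05

    # wild type + two repair-deficient mutants, normoxia and <1% hypoxia
    line = "SYN-WT"
    lethality[line] = draw_ks()
    hrf_wt = float(rng.uniform(2.0, 2.5))
    truth.hrf[(line, 0.5)] = hrf_wt
    conditions.append(ConditionSpec(line))
    conditions.append(ConditionSpec(line, o2_percent=0.5, hrf=hrf_wt))
    for mutant in ("mutant-1", "mutant-2"):
        rsf = float(rng.uniform(8.0, 15.0))
        rsf = min(rsf, 0.95 / lethality[line][0])
        truth.rsf[(line, mutant)] = rsf
        conditions.append(ConditionSpec(line, rsf=rsf, impairment_label=mutant))
        conditions.append(ConditionSpec(line, o2_percent=0.5, hrf=hrf_wt, rsf=rsf,
                                        impairment_label=mutant))

    # two lines x three inhibitor concentrations, normoxia and 1% hypoxia
    for line in ("SYN-F", "SYN-G"):
        lethality[line] = draw_ks()
        hrf_1 = float(rng.uniform(1.1, 1.4))
        truth.hrf[(line, 1.0)] = hrf_1
        conditions.append(ConditionSpec(line))
        conditions.append(ConditionSpec(line, o2_percent=1.0, hrf=hrf_1))
        rsfs = np.sort(rng.uniform(1.7, 5.0, size=3))
        for conc, rsf in zip((100.0, 200.0, 500.0), rsfs):
            label = f"ATMi-{conc:.0f}nM"
            truth.rsf[(line, label)] = float(rsf)
            conditions.append(ConditionSpec(line, rsf=float(rsf),
                                            impairment_label=label, drug_conc_nM=conc))
            conditions.append(ConditionSpec(line, o2_percent=1.0, hrf=hrf_1,
                                            rsf=float(rsf), impairment_label=label,
                                            drug_conc_nM=conc))

    truth.lethality = lethality
    frames = []
    sub_seed = int(rng.integers(0, 2**31 - 1))
    for i, cond in enumerate(conditions):
        ki, kc = lethality[cond.cell_line]
        spec = GeneratorSpec(
            true_params=ModelParameters(k_idsb=ki, k_cdsb=kc),
            conditions=(cond,),
            doses=doses,
            noise_sigma_log=noise_sigma_log,
            n_replicates=n_replicates,
            seed=(sub_seed + i) % 2**31,
            aggregate=aggregate,
        )
        frames.append(generate_dataset(spec).data)
    truth.dataset = SurvivalDataset(pd.concat(frames, ignore_index=True))
    return truth
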