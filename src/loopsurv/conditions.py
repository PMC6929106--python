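"""Oxygenation and radiosensitization modifiers.

Hypoxia reduces the initial DSB yield: the induction rate under an oxygen
concentration [O2] is ``alpha_dsb / HRF`` where the hypoxia reduction factor
HRF >= 1 either comes from a fit to hypoxic survival data or from the
empirical parameterization

    HRF([O2]) = (m*K + [O2]) / (K + [O2])

with maximal factor ``m`` at zero oxygen and half-effect concentration ``K``
(defaults m = 2.94, K = 0.129 %). Lethality parameters are invariant under
oxygenation changes (oxygen affects induction, not repair), and the
radiosensitization factor RSF acts on the isolated-lesion lethality only and
is invariant under oxygenation — so the two modifiers compose freely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import ModelParameters

__all__ = [
    "OxygenCondition",
    "HrfParameterization",
    "RepairImpairment",
    "NORMOXIA",
    "hrf_from_oxygen",
    "effective_induction_rate",
    "condition_adjusted_params",
]

#: Oxygen concentration (%) of standard incubator normoxia.
NORMOXIC_O2_PERCENT = 20.0


@dataclass(frozen=True)
class HrfParameterization:
    """HRF([O2]) = (m*K + [O2])/(K + [O2]).

    ``m`` is the maximal hypoxia reduction factor at zero oxygen; ``k_half``
    (percent O2) sets the scale of the transition to the normoxic limit 1.
    """

    m: float = 2.94
    k_half: float = 0.129

    def __post_init__(self) -> None:
        if self.m <= 1.0:
            raise ValueError(f"m must exceed 1, got {self.m}")
        if self.k_half <= 0.0:
            raise ValueError(f"k_half must be positive, got {self.k_half}")


@dataclass(frozen=True)
class OxygenCondition:
    """Oxygenation context of an irradiation.

    ``hrf`` is the hypoxia reduction factor on DSB induction; 1 is the
    normoxic reference. ``source`` records how the value was obtained:
    ``"fitted"`` (from hypoxic survival data), ``"parameterized"``
    (from :func:`hrf_from_oxygen`), or ``"fixed"`` (asserted, e.g. normoxia).
    ``allow_hyperoxia`` must be set explicitly to accept hrf < 1.
    """

    o2_percent: float = NORMOXIC_O2_PERCENT
    hrf: float = 1.0
    source: str = "fixed"
    allow_hyperoxia: bool = False

    def __post_init__(self) -> None:
        if self.o2_percent < 0:
            raise ValueError(f"oxygen concentration must be non-negative, got {self.o2_percent}")
        if self.hrf < 1.0 and not self.allow_hyperoxia:
            raise ValueError(
                f"hrf = {self.hrf} < 1 (hyperoxia) rejected; pass allow_hyperoxia=True "
                "to accept it deliberately"
            )
        if self.hrf <= 0:
            raise ValueError("hrf must be positive")
        if self.source not in ("fitted", "parameterized", "fixed"):
            raise ValueError(f"unknown hrf source {self.source!r}")

    @classmethod
    def from_oxygen(
        cls, o2_percent: float, par: HrfParameterization | None = None
    ) -> "OxygenCondition":
        """Build a condition with HRF from the oxygen parameterization."""
        par = par or HrfParameterization()
        return cls(
            o2_percent=o2_percent,
            hrf=hrf_from_oxygen(par, o2_percent),
            source="parameterized",
        )

    @classmethod
    def fitted(cls, hrf: float, o2_percent: float = float("nan")) -> "OxygenCondition":
        """Build a condition carrying an HRF fitted from survival data."""
        return cls(o2_percent=o2_percent if not math.isnan(o2_percent) else 0.0,
                   hrf=hrf, source="fitted")


#: The normoxic reference condition (HRF = 1 by definition of the fit protocol).
NORMOXIA = OxygenCondition()


@dataclass(frozen=True)
class RepairImpairment:
    """DSB-repair impairment: a mutant genotype or a DDR inhibitor at a dose.

    ``rsf = 1`` means repair-proficient/untreated; larger values multiply the
    isolated-lesion lethality.
    """

    label: str = "none"
    rsf: float = 1.0

    def __post_init__(self) -> None:
        if self.rsf < 1.0:
            raise ValueError(f"rsf must be >= 1 (1 = repair-proficient), got {self.rsf}")


#: Untreated, repair-proficient reference.
NO_IMPAIRMENT = RepairImpairment()


def hrf_from_oxygen(par: HrfParameterization, o2_percent: float) -> float:
    """Hypoxia reduction factor at a given oxygen concentration (percent).

    Strictly decreasing in [O2]; tends to ``m`` as [O2] -> 0 and to 1 as
    [O2] -> infinity.
    """
    if o2_percent < 0:
        raise ValueError(f"oxygen concentration must be non-negative, got {o2_percent}")
    return (par.m * par.k_half + o2_percent) / (par.k_half + o2_percent)


def effective_induction_rate(params: ModelParameters, cond: OxygenCondition) -> float:
    """DSB induction rate under the oxygen condition: ``alpha_dsb / hrf``."""
    return params.alpha_dsb / cond.hrf


def condition_adjusted_params(
    params: ModelParameters,
    cond: OxygenCondition = NORMOXIA,
    imp: RepairImpairment = NO_IMPAIRMENT,
) -> tuple[ModelParameters, float]:
    """Apply the treatment context: scaled induction rate plus the RSF to use.

    Returns parameters with ``alpha_dsb`` divided by the condition's HRF
    (lethality parameters untouched — oxygen affects induction only) and the
    RSF multiplier to pass to the survival evaluators. The two modifiers act
    on disjoint parameters, so their composition order is immaterial.
    """
    return params.with_alpha(effective_induction_rate(params, cond)), imp.rsf
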