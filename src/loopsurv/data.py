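"""Tabular container for clonogenic survival measurements.

A :class:`SurvivalDataset` wraps a pandas DataFrame with one row per measured
surviving fraction, keyed by cell line, oxygen concentration and repair
impairment. It is the interchange object between the CSV layer, the synthetic
generator and the fitting estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset", "REQUIRED_COLUMNS", "OPTIONAL_COLUMNS", "UNTREATED_LABEL"]

REQUIRED_COLUMNS = (
    "cell_line",
    "o2_percent",
    "impairment_label",
    "dose_Gy",
    "surviving_fraction",
)
OPTIONAL_COLUMNS = ("drug_conc_nM", "sf_sem")

#: Impairment label of repair-proficient, untreated cells.
UNTREATED_LABEL = "none"

#: Oxygen percentages at or above this are treated as the normoxic reference.
NORMOXIC_THRESHOLD = 19.0


@dataclass
class SurvivalDataset:
    """Validated clonogenic survival records.

    Each record carries: ``cell_line`` (label), ``o2_percent`` (%),
    ``impairment_label`` (mutant name or drug+concentration; ``"none"`` for
    untreated), ``dose_Gy``, ``surviving_fraction`` in (0, 1], and optionally
    ``drug_conc_nM`` and ``sf_sem`` (standard error of the surviving
    fraction).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).reset_index(drop=True)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        for col in ("o2_percent", "dose_Gy", "surviving_fraction", "drug_conc_nM", "sf_sem"):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as err:
                raise ValueError(f"column {col!r} contains non-numeric values: {err}") from err
        self._check_rows(df)
        self.data = df

    @staticmethod
    def _check_rows(df: pd.DataFrame) -> None:
        for idx, row in df.iterrows():
            if not np.isfinite(row["dose_Gy"]) or row["dose_Gy"] < 0:
                raise ValueError(f"row {idx}: dose_Gy must be a finite non-negative number, "
                                 f"got {row['dose_Gy']}")
            sf = row["surviving_fraction"]
            if not np.isfinite(sf) or sf <= 0 or sf > 1:
                raise ValueError(
                    f"row {idx}: surviving_fraction must lie in (0, 1], got {sf} "
                    "(a value of exactly 0 cannot be fitted in log space)"
                )
            if not np.isfinite(row["o2_percent"]) or row["o2_percent"] < 0:
                raise ValueError(f"row {idx}: o2_percent must be non-negative, "
                                 f"got {row['o2_percent']}")

    def __len__(self) -> int:
        return len(self.data)

    def subset(
        self,
        cell_line: str | None = None,
        o2_percent: float | None = None,
        impairment_label: str | None = None,
        normoxic: bool | None = None,
    ) -> "SurvivalDataset":
        """Filter records; ``normoxic=True/False`` selects by the 19% threshold."""
        df = self.data
        if cell_line is not None:
            df = df[df["cell_line"] == cell_line]
        if o2_percent is not None:
            df = df[np.isclose(df["o2_percent"], o2_percent)]
        if impairment_label is not None:
            df = df[df["impairment_label"] == impairment_label]
        if normoxic is True:
            df = df[df["o2_percent"] >= NORMOXIC_THRESHOLD]
        elif normoxic is False:
            df = df[df["o2_percent"] < NORMOXIC_THRESHOLD]
        return SurvivalDataset(df.reset_index(drop=True))

    @property
    def doses(self) -> np.ndarray:
        return self.data["dose_Gy"].to_numpy(dtype=float)

    @property
    def surviving_fractions(self) -> np.ndarray:
        return self.data["surviving_fraction"].to_numpy(dtype=float)

    @property
    def sf_sems(self) -> np.ndarray:
        return self.data["sf_sem"].to_numpy(dtype=float)

    def cell_lines(self) -> list[str]:
        return sorted(self.data["cell_line"].unique())

    def conditions(self, cell_line: str) -> pd.DataFrame:
        """Distinct (o2_percent, impairment_label) pairs for one cell line."""
        df = self.data[self.data["cell_line"] == cell_line]
        return (
            df[["o2_percent", "impairment_label"]]
            .drop_duplicates()
            .sort_values(["o2_percent", "impairment_label"], ascending=[False, True])
            .reset_index(drop=True)
        )

    def check_fittable(self, min_distinct_doses: int = 3) -> None:
        """Require enough distinct nonzero doses for a curve fit."""
        nonzero = self.data[self.data["dose_Gy"] > 0]
        n = nonzero["dose_Gy"].nunique()
        if n < min_distinct_doses:
            raise ValueError(
                f"need at least {min_distinct_doses} distinct nonzero doses to fit a "
                f"survival curve, found {n}"
            )
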