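"""CSV input/output and run configuration.

The single tabular dialect is comma-separated UTF-8 with a header row and
dot decimals. Survival files carry the columns
``cell_line, o2_percent, impairment_label, drug_conc_nM, dose_Gy,
surviving_fraction, sf_sem`` (the last two of which are optional on input).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .data import OPTIONAL_COLUMNS, REQUIRED_COLUMNS, SurvivalDataset

__all__ = ["read_survival_csv", "write_survival_csv", "RunConfig"]


def read_survival_csv(path: str | Path) -> SurvivalDataset:
    """Read and validate a survival CSV; errors name the offending row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"survival file not found: {path}")
    df = pd.read_csv(path)
    try:
        return SurvivalDataset(df)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_survival_csv(dataset: SurvivalDataset, path: str | Path) -> Path:
    """Write a dataset in the canonical column order; round-trips losslessly."""
    path = Path(path)
    extra = [c for c in dataset.data.columns
             if c not in REQUIRED_COLUMNS and c not in OPTIONAL_COLUMNS]
    cols = list(REQUIRED_COLUMNS) + [c for c in OPTIONAL_COLUMNS
                                     if c in dataset.data.columns] + extra
    dataset.data[cols].to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Model constants, solver and Monte Carlo settings for a run.

    Defaults are the standard published constants: induction rate 5e-3
    DSB/(Mbp*Gy), 6 Gbp nuclear DNA, 2 Mbp loops, oxygen parameterization
    m = 2.94, K = 0.129%.
    """

    alpha_dsb: float = 5e-3
    dna_content: float = 6000.0
    loop_size: float = 2.0
    hrf_m: float = 2.94
    hrf_k_half: float = 0.129
    n_iter: int = 100_000
    seed: int = 0
    k_lower: float = 1e-6
    k_upper: float = 1.0
    hrf_upper: float = 10.0
    n_starts: int = 5
    weighted: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha_dsb", "dna_content", "loop_size", "hrf_m", "hrf_k_half"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path | None = None) -> str:
        """Serialize as a flat key-value document (idempotent round-trip)."""
        text = yaml.safe_dump(asdict(self), sort_keys=True, default_flow_style=False)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        path = Path(source)
        text = path.read_text(encoding="utf-8") if path.exists() else str(source)
        payload = yaml.safe_load(text) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**payload)

    def config_hash(self) -> str:
        """Short digest identifying the exact configuration of a run."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
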