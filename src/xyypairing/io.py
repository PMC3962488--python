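"""Readers/writers for the tabular formats and the run configuration.

All tables are plain delimited text (comma or tab, sniffed).  Vial-count
tables carry the canonical six class columns (XYY crosses) or the four
control-cross columns, integer counts, plus free metadata columns.  The run
configuration is YAML/JSON with a strict schema: unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pairing import CLASS_ORDER, PairingMixture, ViabilityVector
from .simulate import CONTROL_CLASS_ORDER, VialDesign

__all__ = [
    "read_vial_counts",
    "write_vial_counts",
    "read_ct_table",
    "RunConfig",
]


def _sniff_read(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_vial_counts(path) -> pd.DataFrame:
    """Read and validate a per-vial count table (CSV or TSV).

    The header must contain either the six XYY class labels or the four
    control-cross labels; counts must be nonnegative integers.  Errors name
    every offending cell.
    """
    df = _sniff_read(path)
    cols = set(df.columns)
    if set(CLASS_ORDER) <= cols:
        classes = list(CLASS_ORDER)
    elif set(CONTROL_CLASS_ORDER) <= cols:
        classes = list(CONTROL_CLASS_ORDER)
    else:
        raise ValueError(
            f"{path}: header must contain class columns {list(CLASS_ORDER)} "
            f"or {list(CONTROL_CLASS_ORDER)}; found {sorted(cols)}"
        )
    bad: list[str] = []
    for c in classes:
        col = pd.to_numeric(df[c], errors="coerce")
        for i, v in col.items():
            if pd.isna(v) or v != int(v):
                bad.append(f"row {i}, column {c!r}: non-integer {df.at[i, c]!r}")
            elif v < 0:
                bad.append(f"row {i}, column {c!r}: negative count {int(v)}")
    if bad:
        raise ValueError(f"{path}: invalid counts:\n  " + "\n  ".join(bad))
    df[classes] = df[classes].astype(np.int64)
    return df


def write_vial_counts(df: pd.DataFrame, path) -> None:
    """Write a vial-count table as CSV (round-trips with the reader)."""
    df.to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format qPCR Ct table (sample, replicate, amplicon, ct)."""
    df = _sniff_read(path)
    missing = {"sample", "replicate", "amplicon", "ct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: Ct table is missing columns {sorted(missing)}")
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    if (df["ct"] <= 0).any():
        raise ValueError(f"{path}: Ct values must be positive cycles")
    return df


_ANALYSIS_KEYS = {"level", "alpha", "df", "n_boot"}
_SIMULATION_KEYS = {
    "mixture",
    "viability",
    "n_vials",
    "mean_vial_size",
    "size_dispersion",
    "overdispersion_concentration",
}
_TOP_KEYS = {"seed", "output_dir", "analysis", "simulation"}


@dataclass
class RunConfig:
    """Validated run configuration for the command-line pipeline."""

    seed: int = 0
    output_dir: Path = Path(".")
    level: float = 0.975
    alpha: float = 0.05
    df: int = 1000
    n_boot: int = 2000
    mixture: PairingMixture = field(default_factory=PairingMixture.uniform)
    viability: ViabilityVector = field(default_factory=ViabilityVector.unit)
    design: VialDesign = field(default_factory=VialDesign)

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        analysis = dict(raw.get("analysis") or {})
        if set(analysis) - _ANALYSIS_KEYS:
            raise ValueError(
                f"unknown analysis keys: {sorted(set(analysis) - _ANALYSIS_KEYS)}"
            )
        sim = dict(raw.get("simulation") or {})
        if set(sim) - _SIMULATION_KEYS:
            raise ValueError(
                f"unknown simulation keys: {sorted(set(sim) - _SIMULATION_KEYS)}"
            )
        mixture = PairingMixture(*sim["mixture"]) if "mixture" in sim else PairingMixture.uniform()
        viability = (
            ViabilityVector(sim["viability"]) if "viability" in sim else ViabilityVector.unit()
        )
        design = VialDesign(
            n_vials=int(sim.get("n_vials", VialDesign.n_vials)),
            mean_vial_size=float(sim.get("mean_vial_size", VialDesign.mean_vial_size)),
            size_dispersion=float(sim.get("size_dispersion", VialDesign.size_dispersion)),
            overdispersion_concentration=sim.get("overdispersion_concentration"),
        )
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", ".")),
            level=float(analysis.get("level", 0.975)),
            alpha=float(analysis.get("alpha", 0.05)),
            df=int(analysis.get("df", 1000)),
            n_boot=int(analysis.get("n_boot", 2000)),
            mixture=mixture,
            viability=viability,
            design=design,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_mapping(raw)
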