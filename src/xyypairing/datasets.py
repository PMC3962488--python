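"""Packaged data tables from the XYY pairing study.

Four tables ship with the package, transcribed verbatim from the published
cross summaries:

* ``table1`` — control-cross progeny counts (normal/exceptional by sex) for
  the four Y chromosomes assayed for spontaneous nondisjunction/loss;
* ``table2`` — XYY cross summaries for 11 chromosome combinations: pooled,
  per-vial-mean and per-vial-SD statistics over the six progeny classes
  (percent), sex ratio and aneuploid fraction;
* ``table3`` — per-subset mean/SD of the six class frequencies (proportions)
  for the replicate-vial partitions (by sire: 1/2/3; by transfer time:
  0.1/0.2/0.3; all nine vials: 123) of the two intensively replicated sets;
* ``table4`` — relative rDNA copy number (% of the reference chromosome,
  with pooled SEM) for every Y chromosome in the study.
"""

from __future__ import annotations

from importlib.resources import files

import numpy as np
import pandas as pd

from .pairing import CLASS_ORDER

__all__ = [
    "X_STOCK_FEMALE_NDJ",
    "load_table1",
    "load_table2",
    "load_table3",
    "load_table4",
    "table2_pooled_frequencies",
    "table2_group_stats",
]


#: Spontaneous female nondisjunction assay of the isogenised X stock:
#: (exceptional progeny, total progeny).
X_STOCK_FEMALE_NDJ: tuple[int, int] = (5, 8220)


def _path(name: str):
    return files("xyypairing").joinpath("data", name)


def load_table1() -> pd.DataFrame:
    """Control-cross counts: one row per Y chromosome, four progeny classes."""
    with _path("table1.csv").open() as fh:
        return pd.read_csv(fh)


def load_table2() -> pd.DataFrame:
    """XYY cross summaries: 11 crosses x {pooled, vial_mean, vial_sd} rows."""
    with _path("table2.csv").open() as fh:
        return pd.read_csv(fh)


def load_table3() -> pd.DataFrame:
    """Per-subset class-frequency statistics (proportions) for the scan."""
    with _path("table3.csv").open() as fh:
        return pd.read_csv(fh, dtype={"subset": str, "class": str})


def load_table4() -> pd.DataFrame:
    """Relative rDNA copy numbers (% of reference) with pooled SEMs."""
    with _path("table4.csv").open() as fh:
        return pd.read_csv(fh)


def table2_pooled_frequencies(y1: str, y2: str, renormalize: bool = True) -> pd.Series:
    """Pooled six-class frequencies of one cross as proportions.

    Printed percentages are rounded to one decimal and may sum to 99.9 or
    100.1; ``renormalize`` rescales them onto the simplex (required by the
    mixture estimator).
    """
    t2 = load_table2()
    row = t2[(t2.y1 == y1) & (t2.y2.astype(str) == str(y2)) & (t2.statistic == "pooled")]
    if row.empty:
        raise KeyError(f"no cross {y1}/{y2} in table 2")
    f = row.iloc[0][list(CLASS_ORDER)].astype(float) / 100.0
    if renormalize:
        f = f / f.sum()
    return f


def table2_group_stats(y1: str, y2: str, cls: str) -> tuple[float, float, int]:
    """(vial mean %, vial SD %, n vials) of one class for one cross."""
    t2 = load_table2()
    block = t2[(t2.y1 == y1) & (t2.y2.astype(str) == str(y2))]
    if block.empty:
        raise KeyError(f"no cross {y1}/{y2} in table 2")
    if cls not in CLASS_ORDER:
        raise KeyError(f"unknown class {cls!r}")
    mean = float(block[block.statistic == "vial_mean"].iloc[0][cls])
    sd = float(block[block.statistic == "vial_sd"].iloc[0][cls])
    n = int(block.iloc[0]["n_vials"])
    return mean, sd, n


def _checksums() -> dict[str, int]:
    """CRC32 of each packaged table (guards against silent fixture edits)."""
    import zlib

    out = {}
    for name in ("table1.csv", "table2.csv", "table3.csv", "table4.csv"):
        out[name] = zlib.crc32(_path(name).read_bytes())
    return out
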