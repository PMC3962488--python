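"""Relative rDNA copy-number quantification from replicate qPCR Ct values.

Quantification is comparative (2^-ddCt): each replicate's rDNA threshold
cycle is normalised against the multicopy tRNA amplicon run on the same DNA
(dCt = Ct_rDNA - Ct_tRNA), the per-sample mean dCt is compared with the
reference genotype run on the same plate (ddCt), and the relative copy number
is 2^-ddCt expressed as a percentage of the reference.  Amplification
efficiency is taken as 100%; absolute (cardinal) copy numbers are out of
scope — only fractions relative to the reference are reported.

Uncertainty: the SEM of each sample's mean dCt is pooled with the reference's
by root-sum-of-squares on the dCt (log2) scale, then transferred to the
percent scale by the delta method (d/dx 2^-x = -ln2 * 2^-x):

    SEM_% = ln(2) * relative_% * sqrt(SEM_dCt,sample^2 + SEM_dCt,reference^2)

Replicate dCt values are averaged before the exponentiation (mean-dCt-first,
not a mean of per-replicate ratios), which makes the estimator unbiased on
the log2 scale.  Replicate outliers are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import log, sqrt

import numpy as np
import pandas as pd

__all__ = [
    "CtReplicateSet",
    "CopyNumberMeasurement",
    "relative_copy_number",
    "pool_sem",
    "replicates_from_table",
    "copy_number_from_table",
]


@dataclass(frozen=True)
class CtReplicateSet:
    """Replicate (target, normaliser) Ct pairs for one DNA sample."""

    label: str
    ct_target: tuple[float, ...]
    ct_normalizer: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ct_target) == 0 or len(self.ct_normalizer) == 0:
            raise ValueError(f"sample {self.label!r} has no replicates")
        if len(self.ct_target) != len(self.ct_normalizer):
            raise ValueError(
                f"sample {self.label!r}: target and normalizer replicate "
                "counts differ"
            )
        if min(self.ct_target) <= 0 or min(self.ct_normalizer) <= 0:
            raise ValueError("Ct values must be positive cycles")
        if len(self.ct_target) < 3:
            warnings.warn(
                f"sample {self.label!r} has fewer than 3 replicates; "
                "SEM will be unreliable"
            )

    @property
    def n(self) -> int:
        return len(self.ct_target)

    @property
    def delta_ct(self) -> np.ndarray:
        """Per-replicate dCt = Ct_target - Ct_normalizer."""
        return np.asarray(self.ct_target) - np.asarray(self.ct_normalizer)

    @property
    def mean_delta_ct(self) -> float:
        return float(self.delta_ct.mean())

    @property
    def sem_delta_ct(self) -> float:
        """SEM of the mean dCt (0 for a single replicate)."""
        if self.n < 2:
            return 0.0
        return float(self.delta_ct.std(ddof=1) / sqrt(self.n))


@dataclass(frozen=True)
class CopyNumberMeasurement:
    """Relative copy number (% of reference) with pooled SEM."""

    label: str
    relative_fraction: float  # percent of reference
    sem: float  # percent, pooled across sample and reference
    n_replicates: int
    delta_delta_ct: float


def pool_sem(sample_sem: float, reference_sem: float) -> float:
    """Pool two SEMs by root-sum-of-squares (on the dCt scale)."""
    if sample_sem < 0 or reference_sem < 0:
        raise ValueError("SEMs must be nonnegative")
    return sqrt(sample_sem**2 + reference_sem**2)


def relative_copy_number(
    sample: CtReplicateSet, reference: CtReplicateSet
) -> CopyNumberMeasurement:
    """Comparative 2^-ddCt copy number of ``sample`` relative to ``reference``.

    A constant cycle offset shared by all Cts of a plate cancels in dCt, so
    plate-to-plate shifts do not affect the estimate.  The pooled SEM carries
    the reference's replicate uncertainty into the sample's reported error.
    """
    ddct = sample.mean_delta_ct - reference.mean_delta_ct
    fraction_pct = 100.0 * 2.0 ** (-ddct)
    sem_dct = pool_sem(sample.sem_delta_ct, reference.sem_delta_ct)
    sem_pct = log(2.0) * fraction_pct * sem_dct  # delta method through 2^-x
    return CopyNumberMeasurement(
        label=sample.label,
        relative_fraction=fraction_pct,
        sem=sem_pct,
        n_replicates=sample.n,
        delta_delta_ct=float(ddct),
    )


def replicates_from_table(
    table: pd.DataFrame,
    sample: str,
    target: str = "rDNA",
    normalizer: str = "tRNA",
) -> CtReplicateSet:
    """Build a :class:`CtReplicateSet` from a long-format Ct table.

    The table needs columns ``sample, replicate, amplicon, ct`` (the format
    :func:`xyypairing.simulate.simulate_qpcr` emits and the readers accept).
    """
    required = {"sample", "replicate", "amplicon", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns {sorted(missing)}")
    sub = table[table["sample"] == sample]
    if sub.empty:
        raise ValueError(f"no rows for sample {sample!r}")
    wide = sub.pivot_table(index="replicate", columns="amplicon", values="ct")
    for amplicon in (target, normalizer):
        if amplicon not in wide.columns or wide[amplicon].isna().any():
            raise ValueError(
                f"sample {sample!r}: incomplete {amplicon!r} replicates"
            )
    return CtReplicateSet(
        label=sample,
        ct_target=tuple(wide[target].to_numpy()),
        ct_normalizer=tuple(wide[normalizer].to_numpy()),
    )


def copy_number_from_table(
    table: pd.DataFrame,
    sample: str = "sample",
    reference: str = "reference",
    target: str = "rDNA",
    normalizer: str = "tRNA",
) -> CopyNumberMeasurement:
    """One-call quantification from a long-format Ct table."""
    return relative_copy_number(
        replicates_from_table(table, sample, target, normalizer),
        replicates_from_table(table, reference, target, normalizer),
    )
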