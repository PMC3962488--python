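"""Statistical toolkit: difference-of-means intervals, the subset scan,
class-frequency regression, and the required-sample-size calculation.

The workhorse is a Bayesian-flavoured interval for the difference of two
group means summarised by (mean, SD, n).  Two noninformative-prior posteriors
are offered:

* ``equal_var=True`` (default) — common-variance model: the posterior of the
  mean difference is an exact shifted/scaled Student t with
  ``df = n_a + n_b - 2`` and ``scale = s_p * sqrt(1/n_a + 1/n_b)`` where
  ``s_p^2`` pools the two sample variances.  With equal group sizes this is
  also an exactly calibrated frequentist interval (nominal null exclusion
  rate even at n = 3), which matters here because the replicate subsets are
  tiny.
* ``equal_var=False`` — separate variances: the Behrens-Fisher posterior
  approximated by a Welch t, ``scale = sqrt(sd_a^2/n_a + sd_b^2/n_b)`` with
  Welch-Satterthwaite degrees of freedom.  Slightly conservative at n = 3.

With equal group sizes the two scales coincide; only the degrees of freedom
differ, and both readings flag the same single significant comparison in the
packaged replicate-subset scan (a plain normal-quantile interval flags
several more and is rejected as anticonservative at n = 3).

"Level 0.975" follows the two-sided convention: a 97.5% interval uses the
0.9875 t quantile.  Exclusion of zero from the interval is the significance
criterion; no multiple-testing correction is applied across the scan (each
comparison is reported on its own).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupStats",
    "IntervalEstimate",
    "RegressionFit",
    "diff_mean_interval",
    "pairwise_subset_scan",
    "frequency_regression",
    "required_sample_size",
    "SIRE_SUBSETS",
    "TRANSFER_SUBSETS",
]

#: Subset labels for replicate-vial partitions: by sire and by transfer time.
SIRE_SUBSETS: tuple[str, ...] = ("1", "2", "3")
TRANSFER_SUBSETS: tuple[str, ...] = ("0.1", "0.2", "0.3")


@dataclass(frozen=True)
class GroupStats:
    """Mean, SD and size of one group of replicate vials (frequencies in %
    or proportions — any unit, as long as both groups match)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 1:
            raise ValueError("n must be a positive integer")


@dataclass(frozen=True)
class IntervalEstimate:
    """Two-sided interval for a difference of means."""

    level: float
    center: float
    lower: float
    upper: float
    df: float

    @property
    def excludes_zero(self) -> bool:
        return not (self.lower <= 0.0 <= self.upper)


def diff_mean_interval(
    a: GroupStats, b: GroupStats, level: float = 0.975, equal_var: bool = True
) -> IntervalEstimate:
    """Posterior interval for ``mean_a - mean_b`` at two-sided ``level``.

    Both groups need ``n >= 2``.  With both SDs zero the interval degenerates
    to the point difference (``[0, 0]`` for identical means).  See the module
    docstring for the two ``equal_var`` readings.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("interval computation requires n >= 2 in both groups")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    center = a.mean - b.mean
    if equal_var:
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        scale = sqrt(sp2 * (1 / a.n + 1 / b.n))
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        scale = sqrt(va + vb)
        if scale > 0.0:
            df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    if scale == 0.0:
        return IntervalEstimate(level, center, center, center, df=float("inf"))
    t = float(sps.t.ppf(0.5 + level / 2, df))
    return IntervalEstimate(level, center, center - t * scale, center + t * scale, df)


def pairwise_subset_scan(
    subset_stats: pd.DataFrame,
    level: float = 0.975,
    n_per_subset: int = 3,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Scan every within-partition subset pair of every class for a mean shift.

    Parameters
    ----------
    subset_stats : pandas.DataFrame
        Long-format per-subset statistics with columns
        ``chromosome_set, subset, class, mean, sd`` — one row per
        (chromosome set, vial subset, progeny class).  Subsets partition the
        replicate vials two ways: by sire (``1, 2, 3``) and by transfer time
        (``0.1, 0.2, 0.3``); pairs are formed only within a partition, so a
        complete two-set, six-class table yields 2 x 6 x (3 + 3) = 72
        comparisons.
    level : float
        Two-sided interval level (0.975 by convention here).
    n_per_subset : int
        Vials per subset (3 in the packaged design).

    Returns
    -------
    pandas.DataFrame
        Tidy results: one row per comparison with the interval endpoints and
        an ``excludes_zero`` flag.  ``result.attrs["n_significant"]`` holds
        the count of comparisons excluding zero.
    """
    required = {"chromosome_set", "subset", "class", "mean", "sd"}
    missing = required - set(subset_stats.columns)
    if missing:
        raise ValueError(f"subset table is missing columns {sorted(missing)}")
    partitions = (SIRE_SUBSETS, TRANSFER_SUBSETS)
    rows = []
    for (cset, cls), block in subset_stats.groupby(["chromosome_set", "class"], sort=False):
        block = block.set_index(block["subset"].astype(str))
        for partition in partitions:
            present = [s for s in partition if s in block.index]
            if len(present) < len(partition):
                absent = sorted(set(partition) - set(present))
                raise ValueError(
                    f"missing subsets {absent} for set {cset!r}, class {cls!r}"
                )
            for i, si in enumerate(partition):
                for sj in partition[i + 1 :]:
                    ga = GroupStats(block.loc[si, "mean"], block.loc[si, "sd"], n_per_subset)
                    gb = GroupStats(block.loc[sj, "mean"], block.loc[sj, "sd"], n_per_subset)
                    iv = diff_mean_interval(ga, gb, level, equal_var=equal_var)
                    rows.append(
                        {
                            "chromosome_set": cset,
                            "class": cls,
                            "subset_a": si,
                            "subset_b": sj,
                            "center": iv.center,
                            "lower": iv.lower,
                            "upper": iv.upper,
                            "excludes_zero": iv.excludes_zero,
                        }
                    )
    out = pd.DataFrame(rows)
    out.attrs["n_significant"] = int(out["excludes_zero"].sum())
    out.attrs["level"] = level
    return out


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares line with the squared correlation."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def frequency_regression(x, y) -> RegressionFit:
    """OLS regression of class frequency (%) on rDNA copy number (%).

    ``r_squared`` is the squared product-moment correlation (the spreadsheet
    CORREL convention); for a constant response it is 0 by convention
    (slope 0, no trend).  A constant abscissa is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("abscissa (copy number) is constant; slope undefined")
    if np.ptp(y) == 0:
        return RegressionFit(0.0, float(y[0]), 0.0, x.size)
    fit = sps.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=x.size,
    )


def required_sample_size(
    a: GroupStats | tuple[float, float],
    b: GroupStats | tuple[float, float],
    alpha: float = 0.05,
    df: int = 1000,
) -> int:
    """Vials per group required to call the two group means different.

    Hypothesis-testing detectability criterion with separate variances
    (Welch-style) and a fixed, large-df t quantile:

        n = ceil( t(1 - alpha/2, df)^2 * (sd_a^2 + sd_b^2) / (mean_a - mean_b)^2 )

    There is no power term beyond the alpha threshold: n is the size at which
    the observed mean difference would sit exactly at the critical value.
    Monotone decreasing in the absolute mean difference and increasing in
    either SD.  Equal means raise an error (no finite n).
    """
    ma, sa = (a.mean, a.sd) if isinstance(a, GroupStats) else (float(a[0]), float(a[1]))
    mb, sb = (b.mean, b.sd) if isinstance(b, GroupStats) else (float(b[0]), float(b[1]))
    if ma == mb:
        raise ValueError("group means are equal; required n is infinite")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t = float(sps.t.ppf(1 - alpha / 2, df))
    n = t**2 * (sa**2 + sb**2) / (ma - mb) ** 2
    return max(1, ceil(n))
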