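"""Estimation of pairing-configuration frequencies from progeny count tables.

The forward model is linear: with pairing-configuration frequencies
``(pL, pM, pN)`` and no differential viability, the six zygote-class
frequencies are

    f_X = f_12 = (pL + pM)/4,   f_X1 = f_2 = (pM + pN)/4,
    f_X2 = f_1 = (pL + pN)/4,

so the mixture is recovered by the method-of-moments inversion

    pL = 1 - 2 (f_X1 + f_2),  pM = 1 - 2 (f_X2 + f_1),  pN = 1 - 2 (f_X + f_12).

Mixture and per-class viabilities are jointly unidentifiable from six
frequencies, so the estimator assumes unit viability and instead surfaces the
complementary-pair asymmetries (f_X - f_12, etc.) as a viability diagnostic:
under the pure pairing model each difference is zero in expectation, and a
systematic asymmetry indicates postmeiotic inviability rather than pairing
preference.

The module is organised around :class:`PairingFrequencyModel` (built from a
per-vial count table) whose :meth:`~PairingFrequencyModel.fit` returns a
:class:`PairingFitResults` carrying the point estimate, vial-bootstrap
intervals, diagnostics and a ``summary()`` table.  The underlying operations
(:func:`summarize_cross`, :func:`estimate_mixture_moments`,
:func:`estimate_mixture_bootstrap`, :func:`nondisjunction_rate`,
:func:`complementary_covariance`) are plain functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .pairing import (
    ANEUPLOID_CLASSES,
    CLASS_ORDER,
    COMPLEMENTARY_PAIRS,
    FEMALE_CLASSES,
    PairingMixture,
)
from .simulate import CONTROL_CLASS_ORDER

__all__ = [
    "CrossSummary",
    "MixtureEstimate",
    "NondisjunctionRate",
    "summarize_cross",
    "estimate_mixture_moments",
    "estimate_mixture_bootstrap",
    "nondisjunction_rate",
    "complementary_covariance",
    "PairingFrequencyModel",
    "PairingFitResults",
]

_CONTROL_FEMALE = ("female_normal", "female_exceptional")
_CONTROL_EXCEPTIONAL = ("female_exceptional", "male_exceptional")


def _class_columns(counts: pd.DataFrame) -> list[str]:
    """Identify the count columns: the canonical six or the control four."""
    cols = set(counts.columns)
    if set(CLASS_ORDER) <= cols:
        return list(CLASS_ORDER)
    if set(CONTROL_CLASS_ORDER) <= cols:
        return list(CONTROL_CLASS_ORDER)
    raise ValueError(
        "count table must contain either the six XYY class columns "
        f"{CLASS_ORDER} or the four control-cross columns {CONTROL_CLASS_ORDER}; "
        f"got {sorted(counts.columns)}"
    )


def _validate_counts(counts: pd.DataFrame, classes: list[str]) -> np.ndarray:
    arr = counts[classes].apply(pd.to_numeric).to_numpy()
    if arr.size == 0:
        raise ValueError("count table is empty")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return arr


@dataclass
class CrossSummary:
    """Pooled and per-vial summary of one cross (one published-style summary block).

    Pooled statistics come from the summed counts (never from averaging
    per-vial ratios); per-vial statistics treat each vial as an independent
    subpopulation, with SDs on the n-1 denominator.  Frequencies are in
    percent.  ``vial_sd`` is None (flagged) for single-vial tables.
    """

    classes: tuple[str, ...]
    pooled_freq: pd.Series
    vial_mean: pd.Series
    vial_sd: pd.Series | None
    percent_female: float
    percent_aneuploid: float
    n_vials: int
    n_flies: int
    mean_flies_per_vial: float
    sd_flies_per_vial: float | None

    def to_frame(self) -> pd.DataFrame:
        """Serialise as a summary block (statistics x classes, %)."""
        rows = {"pooled": self.pooled_freq, "vial_mean": self.vial_mean}
        if self.vial_sd is not None:
            rows["vial_sd"] = self.vial_sd
        return pd.DataFrame(rows).T


def summarize_cross(counts: pd.DataFrame) -> CrossSummary:
    """Summarise a per-vial count table into pooled and per-vial statistics.

    Works for both table layouts: the six-class XYY crosses (percent
    aneuploid = XXY daughters + XYY sons, i.e. zygotes from X1, X2 and 12
    sperm) and the four-class control crosses (percent aneuploid = the two
    exceptional classes, which include chromosome-loss events).
    """
    classes = _class_columns(counts)
    arr = _validate_counts(counts, classes)
    totals = arr.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("every vial must contain at least one fly")
    n_vials, n_flies = arr.shape[0], int(totals.sum())
    pooled = arr.sum(axis=0) / n_flies
    per_vial = arr / totals[:, None]
    vial_mean = per_vial.mean(axis=0)
    vial_sd = per_vial.std(axis=0, ddof=1) if n_vials > 1 else None
    if classes == list(CLASS_ORDER):
        female = [classes.index(c) for c in FEMALE_CLASSES]
        aneu = [classes.index(c) for c in ANEUPLOID_CLASSES]
    else:
        female = [classes.index(c) for c in _CONTROL_FEMALE]
        aneu = [classes.index(c) for c in _CONTROL_EXCEPTIONAL]
    return CrossSummary(
        classes=tuple(classes),
        pooled_freq=pd.Series(100 * pooled, index=classes),
        vial_mean=pd.Series(100 * vial_mean, index=classes),
        vial_sd=None if vial_sd is None else pd.Series(100 * vial_sd, index=classes),
        percent_female=float(100 * pooled[female].sum()),
        percent_aneuploid=float(100 * pooled[aneu].sum()),
        n_vials=n_vials,
        n_flies=n_flies,
        mean_flies_per_vial=float(totals.mean()),
        sd_flies_per_vial=float(totals.std(ddof=1)) if n_vials > 1 else None,
    )


@dataclass
class MixtureEstimate:
    """Estimated pairing-configuration frequencies.

    ``projected`` flags estimates whose raw moments inversion fell outside the
    simplex (negatives clipped to 0, then renormalised).  The estimator
    assumes unit viability; ``assumes_unit_viability`` records that caveat in
    the output itself because differential zygote viability biases the
    estimate and is not identifiable from the six class frequencies.
    """

    point: PairingMixture
    method: str
    projected: bool = False
    intervals: pd.DataFrame | None = None
    assumes_unit_viability: bool = True

    def as_series(self) -> pd.Series:
        return self.point.as_series()


_MOMENT_PAIRS = {  # component -> complementary pair whose sum it excludes
    "L": ("X1", "2"),
    "M": ("X2", "1"),
    "N": ("X", "12"),
}


def _moments_from_freqs(freqs: np.ndarray) -> np.ndarray:
    """Vectorised moments inversion; ``freqs`` has the canonical class axis last."""
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    comps = [
        1.0 - 2.0 * (freqs[..., idx[a]] + freqs[..., idx[b]])
        for a, b in (_MOMENT_PAIRS["L"], _MOMENT_PAIRS["M"], _MOMENT_PAIRS["N"])
    ]
    return np.stack(comps, axis=-1)


def _project_simplex(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clip negatives to zero and renormalise; returns (projected, was_outside)."""
    outside = (p < 0).any(axis=-1) | (p > 1).any(axis=-1)
    clipped = np.clip(p, 0.0, None)
    total = clipped.sum(axis=-1, keepdims=True)
    return clipped / total, outside


def estimate_mixture_moments(freqs) -> MixtureEstimate:
    """Method-of-moments estimate of ``(pL, pM, pN)`` from six class frequencies.

    Parameters
    ----------
    freqs : array-like or pandas.Series
        Six class frequencies in the canonical order (a Series indexed by the
        class labels is reordered).  Must be nonnegative and sum to 1 within
        1e-6.

    Notes
    -----
    Exact inverse of :func:`~xyypairing.pairing.zygote_distribution` under
    unit viability; biased when zygote classes differ in viability.
    Components outside [0, 1] (possible under sampling noise) are projected
    onto the simplex and flagged via ``projected``.
    """
    if isinstance(freqs, pd.Series):
        freqs = freqs.reindex(list(CLASS_ORDER)).to_numpy()
    f = np.asarray(freqs, dtype=float)
    if f.shape != (6,):
        raise ValueError("expected six class frequencies")
    if (f < 0).any():
        raise ValueError("frequencies must be nonnegative")
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies must sum to 1; got {f.sum()!r}")
    raw = _moments_from_freqs(f / f.sum())
    proj, outside = _project_simplex(raw)
    return MixtureEstimate(
        point=PairingMixture(*proj), method="moments", projected=bool(outside)
    )


def estimate_mixture_bootstrap(
    counts: pd.DataFrame,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> MixtureEstimate:
    """Moments estimate with percentile intervals from a vial bootstrap.

    Vials are resampled with replacement, pooled frequencies recomputed from
    the resampled sums, and the moments inversion applied to each replicate;
    intervals are the percentile interval at ``level`` per component.
    """
    classes = _class_columns(counts)
    if classes != list(CLASS_ORDER):
        raise ValueError("mixture estimation needs the six XYY class columns")
    arr = _validate_counts(counts, classes)
    n_vials = arr.shape[0]
    if n_vials < 2:
        raise ValueError("vial bootstrap requires at least 2 vials")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile intervals")
    point = estimate_mixture_moments(arr.sum(axis=0) / arr.sum())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_vials, size=(n_boot, n_vials))
    boot_counts = arr[idx].sum(axis=1)  # (n_boot, 6)
    boot_freqs = boot_counts / boot_counts.sum(axis=1, keepdims=True)
    boot_p, _ = _project_simplex(_moments_from_freqs(boot_freqs))
    alpha = 1.0 - level
    lower = np.quantile(boot_p, alpha / 2, axis=0)
    upper = np.quantile(boot_p, 1 - alpha / 2, axis=0)
    intervals = pd.DataFrame(
        {
            "level": level,
            "lower": lower,
            "point": point.point.as_array(),
            "upper": upper,
            "bootstrap_se": boot_p.std(axis=0, ddof=1),
        },
        index=["L", "M", "N"],
    )
    return MixtureEstimate(
        point=point.point,
        method="bootstrap",
        projected=point.projected,
        intervals=intervals,
    )


@dataclass
class NondisjunctionRate:
    """Exceptional-progeny rate (percent) with an exact binomial interval."""

    percent: float
    lower: float
    upper: float
    level: float
    n_exceptional: int
    n_total: int


def nondisjunction_rate(counts, level: float = 0.95) -> NondisjunctionRate:
    """Exceptional-progeny rate from four-class control counts.

    Accepts a control-cross table, the four counts in the canonical control
    order, or a bare ``(n_exceptional, n_total)`` pair.  The interval is
    Clopper-Pearson (exact binomial) at ``level``, so a zero numerator still
    yields a positive upper bound.
    """
    if isinstance(counts, pd.DataFrame):
        arr = _validate_counts(counts, list(CONTROL_CLASS_ORDER)).sum(axis=0)
    else:
        arr = np.asarray(counts, dtype=np.int64)
        if arr.shape == (2,):
            n_exc, total = int(arr[0]), int(arr[1])
            if total == 0:
                raise ValueError("control cross has no progeny")
            if not 0 <= n_exc <= total:
                raise ValueError("need 0 <= n_exceptional <= n_total")
            lo, hi = proportion_confint(n_exc, total, alpha=1 - level, method="beta")
            return NondisjunctionRate(
                100 * n_exc / total, 100 * float(lo), 100 * float(hi),
                level, n_exc, total,
            )
        if arr.shape != (4,):
            raise ValueError("expected four control-cross class counts")
    total = int(arr.sum())
    if total == 0:
        raise ValueError("control cross has no progeny")
    idx = [CONTROL_CLASS_ORDER.index(c) for c in _CONTROL_EXCEPTIONAL]
    n_exc = int(arr[idx].sum())
    lo, hi = proportion_confint(n_exc, total, alpha=1 - level, method="beta")
    return NondisjunctionRate(
        percent=100 * n_exc / total,
        lower=100 * float(lo),
        upper=100 * float(hi),
        level=level,
        n_exceptional=n_exc,
        n_total=total,
    )


def complementary_covariance(counts: pd.DataFrame) -> pd.Series:
    """Across-vial correlation of the three complementary class pairs.

    Returns the product-moment correlation of per-vial frequencies for
    X vs 12, X1 vs 2 and X2 vs 1.  If vials fluctuate because the pairing
    mixture itself varies, complementary classes share a common factor and
    co-vary positively; pure multinomial noise induces the slightly negative
    ``-p_i p_j / n`` covariance.  Pairs with a zero-variance member are
    flagged NaN.
    """
    classes = _class_columns(counts)
    if classes != list(CLASS_ORDER):
        raise ValueError("complementary covariance needs the six XYY class columns")
    arr = _validate_counts(counts, classes)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 vials to estimate correlations")
    freqs = arr / arr.sum(axis=1, keepdims=True)
    out = {}
    for a, b in COMPLEMENTARY_PAIRS:
        x = freqs[:, classes.index(a)]
        y = freqs[:, classes.index(b)]
        if x.std() == 0 or y.std() == 0:
            out[f"{a}~{b}"] = np.nan
        else:
            out[f"{a}~{b}"] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="correlation")


class PairingFrequencyModel:
    """Pairing-configuration frequency model for one XYY cross.

    Built from a per-vial count table over the six canonical classes (plus
    optional metadata columns).  ``fit()`` estimates ``(pL, pM, pN)`` by the
    moments inversion under the unit-viability assumption and attaches
    vial-bootstrap uncertainty and viability diagnostics.

    Examples
    --------
    >>> from xyypairing import simulate, inference, pairing
    >>> counts = simulate.simulate_xyy_vials(
    ...     pairing.PairingMixture(0.2, 0.3, 0.5), seed=1,
    ...     design=simulate.VialDesign(n_vials=30))
    >>> res = inference.PairingFrequencyModel(counts).fit(seed=1)
    >>> res.params.round(2)  # doctest: +SKIP
    """

    def __init__(self, counts: pd.DataFrame):
        classes = _class_columns(counts)
        if classes != list(CLASS_ORDER):
            raise ValueError("PairingFrequencyModel needs the six XYY class columns")
        _validate_counts(counts, classes)
        self.counts = counts.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PairingFrequencyModel":
        return cls(df)

    def fit(
        self, method: str = "moments", n_boot: int = 2000,
        level: float = 0.95, seed: int = 0,
    ) -> "PairingFitResults":
        """Fit the mixture; ``method`` is "moments" (point only when the table
        has a single vial) with bootstrap uncertainty whenever >= 2 vials."""
        if method not in {"moments", "bootstrap"}:
            raise ValueError(f"unknown fit method {method!r}")
        summary = summarize_cross(self.counts)
        if method == "bootstrap" or len(self.counts) >= 2:
            est = estimate_mixture_bootstrap(
                self.counts, n_boot=n_boot, level=level, seed=seed
            )
        else:
            est = estimate_mixture_moments(
                self.counts[list(CLASS_ORDER)].iloc[0]
                / self.counts[list(CLASS_ORDER)].iloc[0].sum()
            )
        return PairingFitResults(model=self, estimate=est, cross_summary=summary)


@dataclass
class PairingFitResults:
    """Results of :meth:`PairingFrequencyModel.fit`.

    ``params`` are the estimated configuration frequencies; ``conf_int()``
    returns the vial-bootstrap percentile intervals; ``diagnostics`` carries
    the complementary-pair frequency asymmetries (zero in expectation under
    unit viability) and their across-vial correlations.
    """

    model: PairingFrequencyModel
    estimate: MixtureEstimate
    cross_summary: CrossSummary

    def __post_init__(self) -> None:
        self.params = self.estimate.as_series()
        pooled = self.cross_summary.pooled_freq
        self.diagnostics = pd.DataFrame(
            {
                "freq_diff_pct": {
                    f"{a}~{b}": pooled[a] - pooled[b] for a, b in COMPLEMENTARY_PAIRS
                },
                "vial_correlation": (
                    complementary_covariance(self.model.counts)
                    if len(self.model.counts) >= 3
                    else np.nan
                ),
            }
        )

    @property
    def bse(self) -> pd.Series | None:
        if self.estimate.intervals is None:
            return None
        return self.estimate.intervals["bootstrap_se"].rename("bse")

    def conf_int(self) -> pd.DataFrame | None:
        if self.estimate.intervals is None:
            return None
        return self.estimate.intervals[["level", "lower", "upper"]]

    def summary(self) -> str:
        s = self.cross_summary
        lines = [
            "Pairing-configuration frequency fit (2+1 model, moments inversion)",
            f"  vials: {s.n_vials}   flies: {s.n_flies}   "
            f"%female: {s.percent_female:.1f}   %aneuploid: {s.percent_aneuploid:.1f}",
            "  assumes unit zygote viability; projected onto simplex: "
            f"{self.estimate.projected}",
            "",
            "  config   estimate" + ("      lower      upper" if self.conf_int() is not None else ""),
        ]
        ci = self.conf_int()
        for name in ("L", "M", "N"):
            row = f"  {name:>6}   {self.params[name]:8.4f}"
            if ci is not None:
                row += f"   {ci.loc[name, 'lower']:8.4f}   {ci.loc[name, 'upper']:8.4f}"
            lines.append(row)
        lines += [
            "",
            "  complementary-pair asymmetry (% points; ~0 under unit viability):",
        ]
        for pair, diff in self.diagnostics["freq_diff_pct"].items():
            lines.append(f"    {pair:>6}: {diff:+.2f}")
        return "\n".join(lines)
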