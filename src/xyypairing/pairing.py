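"""Probabilistic "2+1" pairing model for XYY Drosophila melanogaster males.

An XYY male carries three sex chromosomes — one X and two distinguishable Y
chromosomes (called ``Y1``, the full-length marked Y, and ``Y2``, the Y whose
rDNA array is under evaluation) — that must resolve to two poles at meiosis I.
Under the 2+1 model two of the three chromosomes pair and disjoin faithfully
while the third moves to either pole at random.  Three pairing configurations
are possible:

========  ===========  =========
label     paired       unpaired
========  ===========  =========
``L``     X with Y1    Y2
``M``     X with Y2    Y1
``N``     Y1 with Y2   X
========  ===========  =========

Each configuration produces four equiprobable sperm karyotypes, and together
the three configurations generate exactly six sperm classes, written in the
canonical order ``X, 12, X1, 2, X2, 1`` (digits name the Y chromosomes a sperm
carries; ``X2`` is a sperm with the X and Y2).  Fertilisation of a normal
X-bearing egg turns each sperm class into one zygote class of the same name,
optionally re-weighted by a per-class relative viability to model postmeiotic
embryonic inviability of aneuploid zygotes.

Nullo-XY sperm, chromosome loss and meiosis-II errors are outside the model:
the six-class space is closed (control crosses put such events below 1%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_ORDER",
    "FEMALE_CLASSES",
    "ANEUPLOID_CLASSES",
    "COMPLEMENTARY_PAIRS",
    "GAMETE_CHROMOSOMES",
    "PairingConfiguration",
    "CONFIGURATIONS",
    "PairingMixture",
    "ViabilityVector",
    "MarkerTable",
    "Phenotype",
    "gamete_distribution",
    "zygote_distribution",
    "expected_sex_ratio",
    "phenotype_of",
]

#: Canonical sperm/zygote class order used for every array and table.
CLASS_ORDER: tuple[str, ...] = ("X", "12", "X1", "2", "X2", "1")

#: Chromosome content of each sperm class.
GAMETE_CHROMOSOMES: Mapping[str, frozenset[str]] = {
    "X": frozenset({"X"}),
    "12": frozenset({"Y1", "Y2"}),
    "X1": frozenset({"X", "Y1"}),
    "2": frozenset({"Y2"}),
    "X2": frozenset({"X", "Y2"}),
    "1": frozenset({"Y1"}),
}

#: Classes producing daughters (X-bearing sperm meeting an X egg).
FEMALE_CLASSES: tuple[str, ...] = ("X", "X1", "X2")

#: Sex-chromosome aneuploid zygotes: XXY daughters (X1, X2 sperm) and XYY
#: sons (12 sperm).
ANEUPLOID_CLASSES: tuple[str, ...] = ("X1", "X2", "12")

#: Complementary class pairs — the two products of the same pairing
#: configuration, whose model frequencies are equal absent viability effects.
COMPLEMENTARY_PAIRS: tuple[tuple[str, str], ...] = (
    ("X", "12"),
    ("X1", "2"),
    ("X2", "1"),
)

_SIMPLEX_TOL = 1e-9

_CHROMOSOMES_TO_CLASS = {chroms: label for label, chroms in GAMETE_CHROMOSOMES.items()}


@dataclass(frozen=True)
class PairingConfiguration:
    """One 2+1 arrangement: a faithfully disjoining pair plus a free rider."""

    label: str
    paired: frozenset[str]
    unpaired: str

    def __post_init__(self) -> None:
        if self.paired | {self.unpaired} != {"X", "Y1", "Y2"}:
            raise ValueError(
                f"configuration {self.label!r} must partition X, Y1, Y2; "
                f"got paired={set(self.paired)}, unpaired={self.unpaired!r}"
            )


CONFIGURATIONS: Mapping[str, PairingConfiguration] = {
    "L": PairingConfiguration("L", frozenset({"X", "Y1"}), "Y2"),
    "M": PairingConfiguration("M", frozenset({"X", "Y2"}), "Y1"),
    "N": PairingConfiguration("N", frozenset({"Y1", "Y2"}), "X"),
}


@dataclass(frozen=True)
class PairingMixture:
    """Frequencies ``(pL, pM, pN)`` of the three pairing configurations.

    The three components must lie on the probability simplex; inputs off the
    simplex by no more than 1e-9 are renormalised, larger deviations raise
    ``ValueError``.
    """

    pL: float
    pM: float
    pN: float

    def __post_init__(self) -> None:
        p = np.array([self.pL, self.pM, self.pN], dtype=float)
        if np.any(p < -_SIMPLEX_TOL) or np.any(p > 1 + _SIMPLEX_TOL):
            raise ValueError(f"mixture components must lie in [0, 1]; got {p}")
        total = float(p.sum())
        if abs(total - 1.0) > _SIMPLEX_TOL:
            raise ValueError(
                f"mixture components must sum to 1 (tolerance {_SIMPLEX_TOL}); "
                f"got sum {total!r}"
            )
        p = np.clip(p, 0.0, 1.0) / np.clip(p, 0.0, 1.0).sum()
        object.__setattr__(self, "pL", float(p[0]))
        object.__setattr__(self, "pM", float(p[1]))
        object.__setattr__(self, "pN", float(p[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.pL, self.pM, self.pN], dtype=float)

    def as_series(self) -> pd.Series:
        return pd.Series(self.as_array(), index=["L", "M", "N"], name="probability")

    @classmethod
    def uniform(cls) -> "PairingMixture":
        return cls(1 / 3, 1 / 3, 1 / 3)


class ViabilityVector:
    """Relative viability of each of the six zygote classes.

    Viabilities are nonnegative multiplicative weights applied to the zygote
    distribution before renormalisation.  They are canonicalised so the
    largest weight is 1 (only ratios matter).  ``ViabilityVector.unit()`` is
    the no-inviability reference.
    """

    def __init__(self, values: Mapping[str, float] | Iterable[float]):
        if isinstance(values, Mapping):
            unknown = set(values) - set(CLASS_ORDER)
            if unknown:
                raise ValueError(f"unknown zygote classes: {sorted(unknown)}")
            arr = np.array([float(values.get(c, 1.0)) for c in CLASS_ORDER])
        else:
            arr = np.asarray(list(values), dtype=float)
            if arr.shape != (6,):
                raise ValueError("viability vector needs one weight per class (6)")
        if np.any(arr < 0):
            raise ValueError("viabilities must be nonnegative")
        if not np.any(arr > 0):
            raise ValueError("at least one class must be viable")
        self.values = arr / arr.max()

    @classmethod
    def unit(cls) -> "ViabilityVector":
        return cls(np.ones(6))

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=CLASS_ORDER, name="viability")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        pairs = ", ".join(f"{c}={v:g}" for c, v in zip(CLASS_ORDER, self.values))
        return f"ViabilityVector({pairs})"


def gamete_distribution(config: str | PairingConfiguration) -> pd.Series:
    """Sperm-class distribution produced by one pairing configuration.

    The paired chromosomes disjoin to opposite poles; the unpaired chromosome
    joins either pole with probability 1/2, giving probability 1/4 on exactly
    four of the six sperm classes.

    Parameters
    ----------
    config : {"L", "M", "N"} or PairingConfiguration

    Returns
    -------
    pandas.Series
        Probabilities indexed by the canonical class order.
    """
    if isinstance(config, str):
        try:
            config = CONFIGURATIONS[config]
        except KeyError:
            raise ValueError(
                f"unknown pairing configuration {config!r}; expected L, M or N"
            ) from None
    a, b = sorted(config.paired)
    u = config.unpaired
    dist = pd.Series(0.0, index=list(CLASS_ORDER), name="probability")
    for pole in ({a}, {a, u}, {b}, {b, u}):
        dist[_CHROMOSOMES_TO_CLASS[frozenset(pole)]] += 0.25
    return dist


def zygote_distribution(
    mixture: PairingMixture, viability: ViabilityVector | None = None
) -> pd.Series:
    """Viability-weighted distribution over the six zygote classes.

    The raw class probability is the mixture-weighted sum of the three
    configuration gamete distributions; each class is then multiplied by its
    relative viability and the result renormalised.  Under unit viability the
    complementary pairs are exactly equal:

    ``P(X) = P(12) = (pL + pM)/4``,
    ``P(X1) = P(2) = (pM + pN)/4``,
    ``P(X2) = P(1) = (pL + pN)/4``.
    """
    if viability is None:
        viability = ViabilityVector.unit()
    raw = np.zeros(6)
    for label, p in zip(("L", "M", "N"), mixture.as_array()):
        raw += p * gamete_distribution(label).to_numpy()
    weighted = raw * viability.values
    total = weighted.sum()
    if total <= 0:
        raise ValueError("no viable zygote class: all weighted mass is zero")
    return pd.Series(weighted / total, index=list(CLASS_ORDER), name="probability")


def expected_sex_ratio(
    mixture: PairingMixture, viability: ViabilityVector | None = None
) -> float:
    """Expected fraction of daughters among surviving progeny.

    Daughters arise from the X-bearing sperm classes (X, X1, X2).  Under unit
    viability this is exactly 1/2 for every mixture, because each configuration
    sends the X to either pole with probability 1/2.
    """
    dist = zygote_distribution(mixture, viability)
    return float(dist[list(FEMALE_CLASSES)].sum())


@dataclass(frozen=True)
class MarkerTable:
    """Dominant visible markers on the two Y chromosomes.

    The X carries recessive ``y`` (yellow body) and ``w`` (white eyes), so a
    zygote's phenotype reads out which Y chromosomes its sperm carried.  Y2
    (the rDNA-deletion series chromosome) carries a fully expressed ``y+``.
    Y1 is either the Bar-marked Y (``Bar`` eye shape) or the ROMA chromosome
    whose ``y+`` and ``w+`` transgenes sit in heterochromatin and variegate.
    """

    y1_bar: bool  # True: Y1 carries Bar; False: Y1 carries variegating y+ w+

    @classmethod
    def bar(cls) -> "MarkerTable":
        return cls(y1_bar=True)

    @classmethod
    def roma(cls) -> "MarkerTable":
        return cls(y1_bar=False)


@dataclass(frozen=True)
class Phenotype:
    """Observable phenotype of one zygote class under a marker table.

    ``ambiguous`` marks daughters from X1 sperm, which an extra (unmodelled)
    Y2 would render identical in marker phenotype; the ambiguity is resolvable
    only when Y1 is the variegating (ROMA) chromosome, whose mosaic pigment
    pattern distinguishes one marker dose from two.
    """

    sex: str  # "female" | "male"
    body_color: str  # "yellow" | "yellow+" | "yellow+ variegating"
    eye_color: str  # "white" | "white+" | "white+ variegating"
    eye_shape: str  # "Bar" | "round"
    variegated: bool
    ambiguous: bool


def phenotype_of(gamete: str, marker_table: MarkerTable) -> Phenotype:
    """Render the zygote from ``gamete`` + X-bearing egg into its phenotype.

    Deterministic: the marker genes act dominantly on independent traits
    (body colour, eye colour, eye shape), so each of the six classes maps to
    one descriptor.
    """
    try:
        chroms = GAMETE_CHROMOSOMES[gamete]
    except KeyError:
        raise ValueError(f"unknown gamete class {gamete!r}") from None
    has_y1 = "Y1" in chroms
    has_y2 = "Y2" in chroms
    sex = "female" if "X" in chroms else "male"
    roma_present = has_y1 and not marker_table.y1_bar
    if has_y2:
        body = "yellow+"
    elif roma_present:
        body = "yellow+ variegating"
    else:
        body = "yellow"
    eye_color = "white+ variegating" if roma_present else "white"
    eye_shape = "Bar" if (has_y1 and marker_table.y1_bar) else "round"
    variegated = roma_present
    ambiguous = gamete == "X1" and not variegated
    return Phenotype(sex, body, eye_color, eye_shape, variegated, ambiguous)
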