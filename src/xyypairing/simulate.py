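"""Synthetic data generators with the statistical structure the analysis assumes.

Three generators cover every input the pipeline consumes:

* :func:`simulate_xyy_vials` — vial-structured progeny counts over the six
  sperm classes from an XYY sire, with optional Dirichlet-multinomial
  between-vial overdispersion (the "large natural fluctuation in progeny
  types" replicate vials display);
* :func:`simulate_control_cross` — four-class counts from a normal XY control
  cross with a small nondisjunction/loss rate;
* :func:`simulate_qpcr` — replicate qPCR threshold cycles for an rDNA amplicon
  and a multicopy tRNA normaliser, for a sample and the reference genotype.

All generators are bit-reproducible given a seed; independent substreams are
spawned from one :class:`numpy.random.SeedSequence` so the generators never
share state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pairing import CLASS_ORDER, PairingMixture, ViabilityVector, zygote_distribution

__all__ = [
    "VialDesign",
    "ControlCrossSpec",
    "QpcrSpec",
    "CONTROL_CLASS_ORDER",
    "simulate_xyy_vials",
    "simulate_control_cross",
    "simulate_qpcr",
]

#: Column order for control-cross count tables.
CONTROL_CLASS_ORDER: tuple[str, ...] = (
    "female_normal",
    "female_exceptional",
    "male_exceptional",
    "male_normal",
)


@dataclass(frozen=True)
class VialDesign:
    """Replicate-vial layout for an XYY cross.

    Parameters
    ----------
    n_vials : int
        Number of replicate vials (>= 1).
    mean_vial_size : float
        Mean number of scored flies per vial.  Defaults reflect the observed
        cross summaries: roughly 80-200 flies per vial.
    size_dispersion : float
        Standard deviation of the vial size.  0 gives constant-size vials;
        an SD above the Poisson level selects a negative-binomial size model.
    overdispersion_concentration : float or None
        Total concentration of a symmetric-mean Dirichlet perturbation of the
        class probabilities per vial (small = more between-vial spread).
        ``None`` disables overdispersion (pure multinomial vials).
    """

    n_vials: int = 10
    mean_vial_size: float = 120.0
    size_dispersion: float = 45.0
    overdispersion_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.n_vials < 1:
            raise ValueError("n_vials must be >= 1")
        if self.mean_vial_size < 1:
            raise ValueError("mean_vial_size must be >= 1")
        if self.size_dispersion < 0:
            raise ValueError("size_dispersion must be nonnegative")
        if (
            self.overdispersion_concentration is not None
            and not self.overdispersion_concentration > 0
        ):
            raise ValueError("overdispersion_concentration must be positive or None")


@dataclass(frozen=True)
class ControlCrossSpec:
    """Design of a normal XY control cross.

    ``ndj_rate`` is the per-fly probability of an exceptional (aneuploid or
    chromosome-loss) offspring; normal flies split 1:1 between the sexes and
    exceptional flies split evenly between XXY-like daughters and X0-like
    sons (nondisjunction and loss are not distinguishable from counts alone).
    """

    ndj_rate: float = 0.005
    n_total: int = 4000

    def __post_init__(self) -> None:
        if not 0 <= self.ndj_rate <= 1:
            raise ValueError("ndj_rate must be a probability")
        if self.n_total < 1:
            raise ValueError("n_total must be positive")


@dataclass(frozen=True)
class QpcrSpec:
    """Design of a relative rDNA copy-number qPCR experiment.

    ``true_fraction`` is the rDNA template abundance relative to the reference
    genotype (1.0 = reference).  Threshold cycles follow
    ``Ct = baseline - log2(template)/log2(1 + efficiency) + noise`` with
    independent Gaussian cycle noise per well.
    """

    true_fraction: float = 1.0
    amplification_efficiency: float = 1.0
    ct_noise_sd: float = 0.2
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not self.true_fraction > 0:
            raise ValueError("true_fraction must be positive")
        if not 0 < self.amplification_efficiency <= 1:
            raise ValueError("amplification_efficiency must be in (0, 1]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _substream(seed: int, key: int) -> np.random.Generator:
    """Deterministic independent substream ``key`` of the global ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _draw_vial_sizes(design: VialDesign, rng: np.random.Generator) -> np.ndarray:
    """Vial sizes from a mean/SD-matched overdispersed integer model.

    Constant when ``size_dispersion`` is 0, Poisson when the requested SD is
    at or below the Poisson level, negative binomial (mean ``m``, variance
    ``sd**2``) otherwise.  Zero-size vials are redrawn.
    """
    m = design.mean_vial_size
    var = design.size_dispersion**2
    sizes = np.zeros(design.n_vials, dtype=np.int64)
    todo = np.ones(design.n_vials, dtype=bool)
    while todo.any():
        k = int(todo.sum())
        if design.size_dispersion == 0:
            draw = np.full(k, round(m), dtype=np.int64)
        elif var <= m:
            draw = rng.poisson(m, size=k)
        else:
            r = m * m / (var - m)
            p = m / var
            draw = rng.negative_binomial(r, p, size=k)
        sizes[todo] = draw
        todo = sizes == 0
        if design.size_dispersion == 0 and todo.any():  # constant size 0 never resolves
            raise ValueError("mean_vial_size rounds to zero flies per vial")
    return sizes


def simulate_xyy_vials(
    mixture: PairingMixture,
    viability: ViabilityVector | None = None,
    design: VialDesign | None = None,
    seed: int = 0,
    *,
    y1_identity: str = "ROMA",
    y2_identity: str = "10B",
    rdna_fraction: float = 100.0,
) -> pd.DataFrame:
    """Simulate per-vial progeny counts over the six classes from XYY sires.

    Each vial draws a size from the design's integer size model, optionally
    perturbs the expected class probabilities by a Dirichlet draw with mean
    ``zygote_distribution(mixture, viability)`` and total concentration
    ``overdispersion_concentration``, then draws multinomial counts.

    Returns
    -------
    pandas.DataFrame
        One row per vial with the canonical six count columns plus metadata
        columns ``y1_identity, y2_identity, rdna_fraction, sire_id,
        transfer_index``.
    """
    design = design or VialDesign()
    p = zygote_distribution(mixture, viability).to_numpy()
    size_rng = _substream(seed, 0)
    class_rng = _substream(seed, 1)
    sizes = _draw_vial_sizes(design, size_rng)
    counts = np.empty((design.n_vials, 6), dtype=np.int64)
    for i, n in enumerate(sizes):
        if design.overdispersion_concentration is None:
            probs = p
        else:
            probs = class_rng.dirichlet(design.overdispersion_concentration * p)
        counts[i] = class_rng.multinomial(n, probs)
    out = pd.DataFrame(counts, columns=list(CLASS_ORDER))
    out.insert(0, "vial", np.arange(1, design.n_vials + 1))
    out["y1_identity"] = y1_identity
    out["y2_identity"] = y2_identity
    out["rdna_fraction"] = rdna_fraction
    out["sire_id"] = np.arange(1, design.n_vials + 1)
    out["transfer_index"] = 1
    return out


def simulate_control_cross(
    spec: ControlCrossSpec, seed: int = 0
) -> pd.DataFrame:
    """Simulate a four-class control-cross count table (one row).

    Exceptional flies are drawn binomially at ``ndj_rate`` and split evenly
    between the sexes; normal flies split 1:1.
    """
    rng = _substream(seed, 2)
    n_exc = rng.binomial(spec.n_total, spec.ndj_rate)
    n_exc_female = rng.binomial(n_exc, 0.5)
    n_norm = spec.n_total - n_exc
    n_norm_female = rng.binomial(n_norm, 0.5)
    row = {
        "female_normal": n_norm_female,
        "female_exceptional": n_exc_female,
        "male_exceptional": n_exc - n_exc_female,
        "male_normal": n_norm - n_norm_female,
    }
    return pd.DataFrame([row], columns=list(CONTROL_CLASS_ORDER))


#: Nominal clean-template threshold cycles for the two amplicons.
_BASELINE_CT = {"rDNA": 16.0, "tRNA": 22.0}


def simulate_qpcr(spec: QpcrSpec, seed: int = 0) -> pd.DataFrame:
    """Simulate replicate Ct pairs for a sample and the reference genotype.

    The rDNA amplicon of the sample has relative template ``true_fraction``;
    the tRNA normaliser and the reference genotype have relative template 1.
    ``Ct = baseline - log2(template)/log2(1 + efficiency) + N(0, ct_noise_sd)``.

    Returns
    -------
    pandas.DataFrame
        Long format with columns ``sample`` ("sample" | "reference"),
        ``replicate``, ``amplicon`` ("rDNA" | "tRNA") and ``ct``.
    """
    rng = _substream(seed, 3)
    slope = 1.0 / np.log2(1.0 + spec.amplification_efficiency)
    rows = []
    for label, rdna_template in (("sample", spec.true_fraction), ("reference", 1.0)):
        for amplicon, template in (("rDNA", rdna_template), ("tRNA", 1.0)):
            base = _BASELINE_CT[amplicon] - slope * np.log2(template)
            cts = base + rng.normal(0.0, spec.ct_noise_sd, size=spec.n_replicates)
            for rep, ct in enumerate(cts, start=1):
                rows.append((label, rep, amplicon, float(ct)))
    return pd.DataFrame(rows, columns=["sample", "replicate", "amplicon", "ct"])
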