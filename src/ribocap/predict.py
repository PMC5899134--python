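"""Forward burden prediction for single genes and operons.

Builds competitor mRNA species from construct or operon designs, predicts
their normalized in vitro capacity with the competitive translation model,
maps it to an in vivo capacity through a per-condition linear calibration,
and decomposes a measured in vivo capacity into expression and metabolic
burden components.

Each cistron of an operon is modelled as an independent mRNA species at the
promoter-determined transcript concentration: on a polycistronic message
every RBS is a separate ribosome entry point, and the per-gene (gamma, RBS
strength) parameterisation carries no inter-cistron coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .gamma import AssayConfig
from .model import ConstructSpec, normalized_capacity
from .promoters import PROMOTERS, PromoterClass, mrna_concentration

__all__ = [
    "PromoterClass",
    "PROMOTERS",
    "mrna_concentration",
    "Cistron",
    "OperonDesign",
    "CalibrationFit",
    "CalibrationRegistry",
    "BurdenDecomposition",
    "operon_to_species",
    "predict_in_vitro",
    "fit_calibration",
    "predict_in_vivo",
    "decompose_burden",
]


@dataclass(frozen=True)
class Cistron:
    """One coding sequence inside an operon. ``gamma`` may be left unset
    and filled in later from a characterisation table."""

    name: str
    rbs_strength: float
    length_bp: int
    gamma: float | None = None


@dataclass(frozen=True)
class OperonDesign:
    name: str
    promoter: PromoterClass | str
    plasmid_conc: float
    cistrons: tuple[Cistron, ...]

    def __post_init__(self):
        if len(self.cistrons) < 1:
            raise ValueError("an operon needs at least one cistron")
        object.__setattr__(self, "cistrons", tuple(self.cistrons))


def operon_to_species(op: OperonDesign) -> list[ConstructSpec]:
    """One competing mRNA species per cistron, all at the shared
    promoter-determined transcript concentration."""
    conc = mrna_concentration(op.promoter, op.plasmid_conc)
    species = []
    for c in op.cistrons:
        if c.gamma is None:
            raise ValueError(
                f"cistron {c.name!r} of operon {op.name!r} has no gamma value"
            )
        species.append(
            ConstructSpec(
                name=c.name,
                rbs_strength=c.rbs_strength,
                mrna_conc=conc,
                length_bp=c.length_bp,
                gamma=c.gamma,
            )
        )
    return species


def predict_in_vitro(
    design: OperonDesign | ConstructSpec, assay: AssayConfig | None = None
) -> float:
    """Predicted normalized in vitro capacity of a design in the standard
    lysate competition assay."""
    assay = assay or AssayConfig()
    if isinstance(design, ConstructSpec):
        species = [design]
    else:
        species = operon_to_species(design)
    return normalized_capacity(species, assay.model_params)


@dataclass(frozen=True)
class CalibrationFit:
    """Linear map from in vitro to in vivo normalized capacity for one
    (strain, medium) condition: y = slope * x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    condition: str = ""
    n_points: int = 0


def fit_calibration(
    pairs: list[tuple[float, float]], condition: str = ""
) -> CalibrationFit:
    """Ordinary least squares of in vivo on in vitro capacity."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (in_vitro, in_vivo) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("in vitro capacities are all identical; cannot fit a line")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return CalibrationFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        condition=condition,
        n_points=len(x),
    )


class CalibrationRegistry:
    """Per-condition calibration store. Prediction requires an explicit
    condition key; there is no silent default."""

    def __init__(self):
        self._fits: dict[str, CalibrationFit] = {}

    def add(self, fit: CalibrationFit) -> None:
        if not fit.condition:
            raise ValueError("calibration fit must carry a condition label")
        self._fits[fit.condition] = fit

    def get(self, condition: str) -> CalibrationFit:
        try:
            return self._fits[condition]
        except KeyError:
            raise KeyError(
                f"no calibration for condition {condition!r}; "
                f"known: {sorted(self._fits)}"
            ) from None

    def conditions(self) -> list[str]:
        return sorted(self._fits)


def predict_in_vivo(in_vitro_capacity: float, fit: CalibrationFit) -> float:
    """Map an in vitro capacity to in vivo, clipped to [0, 1]."""
    y = fit.slope * in_vitro_capacity + fit.intercept
    if y < 0.0 or y > 1.0:
        warnings.warn(
            f"predicted in vivo capacity {y:.3g} clipped to [0, 1]", stacklevel=2
        )
    return float(np.clip(y, 0.0, 1.0))


@dataclass(frozen=True)
class BurdenDecomposition:
    """Split of measured in vivo burden into parts.

    ``expression_component = 1 - predicted_in_vivo`` is the burden the
    model attributes to competition for expression resources;
    ``metabolic_component = predicted_in_vivo - measured_in_vivo`` is the
    extra capacity loss not explained by expression (e.g. the encoded
    pathway draining host metabolites). A negative metabolic component
    means the model over-predicted the expression burden.
    """

    predicted_in_vivo: float
    measured_in_vivo: float

    @property
    def metabolic_component(self) -> float:
        return self.predicted_in_vivo - self.measured_in_vivo

    @property
    def expression_component(self) -> float:
        return 1.0 - self.predicted_in_vivo

    @property
    def over_predicted(self) -> bool:
        return self.metabolic_component < 0


def decompose_burden(predicted_in_vivo: float, measured_in_vivo: float) -> BurdenDecomposition:
    for name, v in (("predicted", predicted_in_vivo), ("measured", measured_in_vivo)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} in vivo capacity must be in [0, 1], got {v}")
    d = BurdenDecomposition(predicted_in_vivo, measured_in_vivo)
    if d.over_predicted:
        warnings.warn(
            "measured capacity exceeds prediction (negative metabolic component)",
            stacklevel=2,
        )
    return d
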