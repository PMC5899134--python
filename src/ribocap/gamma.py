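"""Inference of the lumped synthesis cost gamma from lysate capacity.

A construct's measured normalized in vitro capacity, together with its known
RBS strength and mRNA length, pins down the one remaining model parameter:
the lumped per-step synthesis rate gamma. Because monitor capacity is
strictly increasing in the competitor's gamma (a cheaper protein sequesters
fewer ribosomes), the inversion is a bracketed scalar root-find on
log(gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model import ConstructSpec, ModelParams, default_params, solve_steady_state
from .promoters import mrna_concentration

__all__ = [
    "AssayConfig",
    "GammaEstimate",
    "CapacityOutOfRangeError",
    "capacity_grid",
    "infer_gamma",
]

GAMMA_BRACKET = (1e-4, 1e2)  # s^-1; encloses all published values with margin


class CapacityOutOfRangeError(ValueError):
    """Measured capacity falls outside what the model can reach on the bracket."""

    def __init__(self, measured: float, achievable: tuple[float, float]):
        lo, hi = achievable
        super().__init__(
            f"measured capacity {measured:.4g} is outside the achievable "
            f"interval [{lo:.4g}, {hi:.4g}] for gamma in the search bracket"
        )
        self.measured = measured
        self.achievable = achievable


@dataclass(frozen=True)
class AssayConfig:
    """Standard lysate competition assay conditions.

    30 nM of monitor plasmid plus 20 nM of test plasmid puts the mix at the
    50 nM DNA saturation point where translational resources limit
    expression.
    """

    monitor_plasmid_conc: float = 30.0
    test_plasmid_conc: float = 20.0
    promoter_class_of_test: str = "strong"
    model_params: ModelParams = field(default_factory=default_params)

    def __post_init__(self):
        if self.monitor_plasmid_conc <= 0 or self.test_plasmid_conc <= 0:
            raise ValueError("plasmid concentrations must be > 0")

    @property
    def test_mrna_conc(self) -> float:
        """mRNA concentration of the test construct in the mix, nM."""
        return mrna_concentration(self.promoter_class_of_test, self.test_plasmid_conc)


@dataclass(frozen=True)
class GammaEstimate:
    gamma: float
    bracket: tuple[float, float]
    achieved_capacity: float
    converged: bool
    #: gamma interval implied by +/- 1 s.e. on capacity spans more than 10x
    wide_interval: bool = False


class _CapacityFn:
    """Monitor capacity as a function of competitor gamma, with the
    monitor-alone rate computed once."""

    def __init__(self, rbs_strength: float, length_bp: int, assay: AssayConfig):
        self.rbs = rbs_strength
        self.length_bp = int(length_bp)
        self.assay = assay
        p = assay.model_params
        self._p = p
        self._alone = solve_steady_state([p.monitor], p).production_rates[0]

    def __call__(self, gamma: float) -> float:
        c = ConstructSpec(
            name="test",
            rbs_strength=self.rbs,
            mrna_conc=self.assay.test_mrna_conc,
            length_bp=self.length_bp,
            gamma=gamma,
        )
        full = solve_steady_state([self._p.monitor, c], self._p)
        return float(full.production_rates[0] / self._alone)


def capacity_grid(
    lengths: list[int],
    gammas: list[float],
    rbs_strength: float,
    assay: AssayConfig | None = None,
) -> np.ndarray:
    """Simulated monitor-capacity heat map over (mRNA length, gamma).

    Entry ``(i, j)`` is the normalized capacity with one competitor of
    length ``lengths[i]`` and synthesis rate ``gammas[j]`` at the assay's
    test mRNA concentration. Capacity falls with length and rises with
    gamma, so the map is monotone along both axes.
    """
    if len(lengths) == 0 or len(gammas) == 0:
        raise ValueError("lengths and gammas must be non-empty")
    assay = assay or AssayConfig()
    out = np.empty((len(lengths), len(gammas)))
    for i, L in enumerate(lengths):
        fn = _CapacityFn(rbs_strength, L, assay)
        for j, g in enumerate(gammas):
            out[i, j] = fn(g)
    return out


def infer_gamma(
    measured_capacity: float,
    rbs_strength: float,
    length_bp: int,
    assay: AssayConfig | None = None,
    tol: float = 1e-4,
    bracket: tuple[float, float] = GAMMA_BRACKET,
    capacity_se: float | None = None,
    on_out_of_range: str = "raise",
) -> GammaEstimate:
    """Recover gamma from a measured normalized in vitro capacity.

    Parameters
    ----------
    measured_capacity : float
        Normalized capacity in (0, 1]; replicate measurements should be
        averaged before inversion.
    rbs_strength, length_bp :
        Known construct properties.
    tol : float
        Relative tolerance on the achieved capacity.
    capacity_se : float, optional
        Standard error of the measured capacity. When given, the gamma
        interval implied by +/- 1 s.e. is evaluated and the estimate is
        flagged ``wide_interval`` if it spans more than a factor of 10
        (near-flat region of the capacity curve).
    on_out_of_range : {"raise", "clip"}
        How to treat measurements outside the model's achievable range.
        "clip" returns the bracket-edge gamma with ``converged=False`` and
        ``wide_interval=True`` — appropriate in batch pipelines where
        measurement noise can push a burden-free construct's capacity
        slightly above the model supremum.

    Raises
    ------
    CapacityOutOfRangeError
        If the measurement lies outside the capacity range the model can
        produce for gamma inside the bracket (for example, any value > 1)
        and ``on_out_of_range="raise"``.
    """
    if not 0 < measured_capacity:
        raise ValueError("measured_capacity must be > 0")
    if on_out_of_range not in ("raise", "clip"):
        raise ValueError("on_out_of_range must be 'raise' or 'clip'")
    assay = assay or AssayConfig()
    lo, hi = bracket
    fn = _CapacityFn(rbs_strength, length_bp, assay)
    cap_lo, cap_hi = fn(lo), fn(hi)
    if not cap_lo <= measured_capacity <= cap_hi:
        if on_out_of_range == "raise":
            raise CapacityOutOfRangeError(measured_capacity, (cap_lo, cap_hi))
        edge, cap_edge = (lo, cap_lo) if measured_capacity < cap_lo else (hi, cap_hi)
        return GammaEstimate(
            gamma=edge, bracket=bracket, achieved_capacity=cap_edge,
            converged=False, wide_interval=True,
        )

    f = lambda lg: fn(10.0**lg) - measured_capacity
    lg = brentq(f, np.log10(lo), np.log10(hi), xtol=1e-6)
    gamma = float(10.0**lg)
    achieved = fn(gamma)
    converged = abs(achieved - measured_capacity) <= tol * max(measured_capacity, 1e-12)

    wide = False
    if capacity_se is not None and capacity_se > 0:
        g_lo = _invert_clipped(fn, measured_capacity - capacity_se, bracket)
        g_hi = _invert_clipped(fn, measured_capacity + capacity_se, bracket)
        wide = g_hi / g_lo > 10.0
    return GammaEstimate(
        gamma=gamma,
        bracket=bracket,
        achieved_capacity=achieved,
        converged=converged,
        wide_interval=wide,
    )


def _invert_clipped(fn: _CapacityFn, target: float, bracket: tuple[float, float]) -> float:
    lo, hi = bracket
    if target <= fn(lo):
        return lo
    if target >= fn(hi):
        return hi
    lg = brentq(lambda l: fn(10.0**l) - target, np.log10(lo), np.log10(hi), xtol=1e-4)
    return float(10.0**lg)
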