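"""Steady-state competitive translation with a shared ribosome pool.

Several mRNA species compete for one finite pool of ribosomes. Each species
is a coarse-grained ribosome-flow chain: a free ribosome binds the RBS of an
mRNA at rate ``a_plus * R_free``, either unbinds (``a_minus``) or initiates
synthesis (``b0``) onto the first elongation site, then hops site-to-site at
the lumped per-step synthesis rate ``gamma`` under hard exclusion (a ribosome
cannot move into an occupied site). One site spans 30 bp — roughly the
10-codon footprint of a ribosome — so an mRNA of length L bp has about L/30
elongation steps. The terminal step releases the ribosome back to the pool.

All rate constants for a construct are tied to the reference (capacity
monitor) rates through its relative RBS strength::

    a_plus  = a_plus_M  * rbs_strength
    a_minus = a_minus_M / rbs_strength
    b0      = b0_M      * rbs_strength

Concentrations are nM, time is seconds; ``b0`` and ``gamma`` are per
10-codon step, written s^-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "ConstructSpec",
    "ModelParams",
    "SpeciesState",
    "SteadyStateResult",
    "ConvergenceError",
    "n_steps",
    "derived_rates",
    "rhs",
    "solve_steady_state",
    "normalized_capacity",
    "default_params",
]

#: one coarse site = 30 bases = 10 codons, the ribosome footprint
SITE_BP = 30


class ConvergenceError(RuntimeError):
    """Steady-state solver failed to reach the requested residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def n_steps(length_bp: int) -> int:
    """Number of elongation steps for a coding sequence of ``length_bp``.

    One step per 30 bp (the ribosome footprint), rounded to the nearest
    integer with ties rounded up, and never fewer than one step.
    """
    if length_bp <= 0:
        raise ValueError(f"length_bp must be positive, got {length_bp}")
    return max(1, int(np.floor(length_bp / SITE_BP + 0.5)))


@dataclass(frozen=True)
class ConstructSpec:
    """One translated unit competing for the ribosome pool.

    Parameters
    ----------
    name : str
        Label for reporting.
    rbs_strength : float
        Translation-initiation efficiency relative to the capacity
        monitor's RBS (monitor = 1).
    mrna_conc : float
        Transcript concentration in the mix, nM.
    length_bp : int
        Coding-sequence length in base pairs (>= 30).
    gamma : float
        Lumped per-step synthesis rate, (10 codons) s^-1. Low gamma means
        costly translation.
    """

    name: str
    rbs_strength: float
    mrna_conc: float
    length_bp: int
    gamma: float

    def __post_init__(self):
        if self.rbs_strength <= 0:
            raise ValueError(f"rbs_strength must be > 0, got {self.rbs_strength}")
        if self.mrna_conc < 0:
            raise ValueError(f"mrna_conc must be >= 0, got {self.mrna_conc}")
        if self.length_bp < SITE_BP:
            raise ValueError(f"length_bp must be >= {SITE_BP}, got {self.length_bp}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")

    @property
    def n_sites(self) -> int:
        return n_steps(self.length_bp)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "rbs_strength": self.rbs_strength,
            "mrna_conc": self.mrna_conc,
            "length_bp": self.length_bp,
            "gamma": self.gamma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConstructSpec":
        return cls(**d)


def _default_monitor() -> ConstructSpec:
    # 30 nM plasmid x 30 mRNA/DNA (strong promoter) = 900 nM; 720 bp sfGFP
    return ConstructSpec(
        name="monitor", rbs_strength=1.0, mrna_conc=900.0, length_bp=720, gamma=1.0
    )


@dataclass(frozen=True)
class ModelParams:
    """Reference rates of the capacity monitor and the shared pool size.

    Defaults are the published simulation set: a_plus_M = 1e-4
    rib^-1 RBS^-1 s^-1, a_minus_M = 200 s^-1, b0_M = 1 s^-1, and a total
    ribosome pool of 2500 nM.
    """

    a_plus_M: float = 1e-4
    a_minus_M: float = 200.0
    b0_M: float = 1.0
    R_total: float = 2500.0
    monitor: ConstructSpec = field(default_factory=_default_monitor)

    def __post_init__(self):
        for name in ("a_plus_M", "a_minus_M", "b0_M", "R_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return {
            "a_plus_M": self.a_plus_M,
            "a_minus_M": self.a_minus_M,
            "b0_M": self.b0_M,
            "R_total": self.R_total,
            "monitor": self.monitor.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        if "monitor" in d:
            d["monitor"] = ConstructSpec.from_dict(d["monitor"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_params() -> ModelParams:
    """Load the packaged default parameter file."""
    ref = resources.files("ribocap").joinpath("params/default_params.json")
    return ModelParams.from_dict(json.loads(ref.read_text()))


def derived_rates(c: ConstructSpec, p: ModelParams) -> tuple[float, float, float]:
    """Per-construct (a_plus, a_minus, b0) from its relative RBS strength."""
    s = c.rbs_strength
    return p.a_plus_M * s, p.a_minus_M / s, p.b0_M * s


@dataclass(frozen=True)
class SpeciesState:
    """Occupancy state of one mRNA species.

    ``rbs_occupancy`` is the probability the RBS is ribosome-bound but not
    yet initiated; ``site_occupancies`` has one entry per elongation site.
    """

    species: ConstructSpec
    rbs_occupancy: float
    site_occupancies: np.ndarray

    @property
    def bound_per_mrna(self) -> float:
        """Ribosomes sequestered per mRNA molecule (RBS + elongating)."""
        return self.rbs_occupancy + float(np.sum(self.site_occupancies))


@dataclass(frozen=True)
class SteadyStateResult:
    """Solver output: occupancies, free pool, and per-species rates.

    ``fluxes[s]`` holds the per-mRNA ribosome flux (s^-1) through each
    transition of species ``s``: initiation, the n-1 internal hops, and the
    terminal release; at steady state these are all equal.
    ``production_rates[s] = gamma_s * terminal occupancy * mrna_conc`` (nM/s).
    """

    states: list[SpeciesState]
    free_ribosomes: float
    production_rates: np.ndarray
    fluxes: list[np.ndarray]
    residual: float
    method: str = "root"


# --- state packing -------------------------------------------------------
# The solver state vector concatenates, per species, [rbs_occupancy,
# x_1 .. x_n].  R_free is always recomputed from conservation.


def _split(y: np.ndarray, species: Sequence[ConstructSpec]) -> list[np.ndarray]:
    out, i = [], 0
    for c in species:
        k = 1 + c.n_sites
        out.append(y[i : i + k])
        i += k
    return out


def _free_ribosomes(y: np.ndarray, species: Sequence[ConstructSpec], p: ModelParams) -> float:
    bound = 0.0
    for c, yc in zip(species, _split(y, species)):
        bound += c.mrna_conc * float(np.sum(yc))
    return p.R_total - bound


def rhs(y: np.ndarray, species: Sequence[ConstructSpec], p: ModelParams) -> np.ndarray:
    """Time derivatives of all occupancies at state ``y``.

    Per species with rates (a_plus, a_minus, b0) and step rate gamma::

        dp/dt   = a_plus*R_free*(1-p) - a_minus*p - b0*p*(1-x_1)
        dx_1/dt = b0*p*(1-x_1) - gamma*x_1*(1-x_2)
        dx_i/dt = gamma*x_{i-1}*(1-x_i) - gamma*x_i*(1-x_{i+1})
        dx_n/dt = gamma*x_{n-1}*(1-x_n) - gamma*x_n      (release to pool)

    ``R_free`` is derived from ribosome conservation, never integrated.
    """
    R_free = _free_ribosomes(y, species, p)
    dy = np.empty_like(y)
    i = 0
    for c in species:
        a_plus, a_minus, b0 = derived_rates(c, p)
        g = c.gamma
        n = c.n_sites
        pr = y[i]
        x = y[i + 1 : i + 1 + n]
        init_flux = b0 * pr * (1.0 - x[0])
        dy[i] = a_plus * R_free * (1.0 - pr) - a_minus * pr - init_flux
        if n == 1:
            dy[i + 1] = init_flux - g * x[0]
        else:
            hop = g * x[:-1] * (1.0 - x[1:])  # flux i -> i+1
            dy[i + 1] = init_flux - hop[0]
            dy[i + 2 : i + n] = hop[:-1] - hop[1:]
            dy[i + n] = hop[-1] - g * x[-1]
        i += 1 + n
    return dy


def _species_fluxes(y: np.ndarray, species: Sequence[ConstructSpec], p: ModelParams) -> list[np.ndarray]:
    out = []
    for c, yc in zip(species, _split(y, species)):
        _, _, b0 = derived_rates(c, p)
        pr, x = yc[0], yc[1:]
        f = np.empty(len(x) + 1)
        f[0] = b0 * pr * (1.0 - x[0])
        if len(x) > 1:
            f[1:-1] = c.gamma * x[:-1] * (1.0 - x[1:])
        f[-1] = c.gamma * x[-1]
        out.append(f)
    return out


def _result_from(y, species, p, method) -> SteadyStateResult:
    res = float(np.max(np.abs(rhs(y, species, p))))
    states = []
    rates = np.empty(len(species))
    for k, (c, yc) in enumerate(zip(species, _split(y, species))):
        states.append(
            SpeciesState(species=c, rbs_occupancy=float(yc[0]), site_occupancies=yc[1:].copy())
        )
        rates[k] = c.gamma * yc[-1] * c.mrna_conc
    return SteadyStateResult(
        states=states,
        free_ribosomes=_free_ribosomes(y, species, p),
        production_rates=rates,
        fluxes=_species_fluxes(y, species, p),
        residual=res,
        method=method,
    )


def _valid(y: np.ndarray, species, p, slack: float = 1e-7) -> bool:
    if np.any(y < -slack) or np.any(y > 1.0 + slack):
        return False
    return _free_ribosomes(y, species, p) >= -slack * p.R_total


def _relax(y0, species, p, tol, t_max=1e8):
    """Integrate the occupancy ODEs until derivatives fall below ``tol``."""
    y, t_span = y0, 2.0e3
    fun = lambda t, yy: rhs(yy, species, p)
    while t_span <= t_max:
        sol = solve_ivp(fun, (0.0, t_span), y, method="LSODA", rtol=1e-10, atol=1e-13)
        if not sol.success:
            break
        y = sol.y[:, -1]
        if np.max(np.abs(rhs(y, species, p))) <= tol:
            return y
        t_span *= 10.0
    return y


def solve_steady_state(
    species: Sequence[ConstructSpec],
    p: ModelParams,
    tol: float = 1e-9,
    method: str = "auto",
) -> SteadyStateResult:
    """Solve for the steady state of the competitive translation system.

    Parameters
    ----------
    species : sequence of ConstructSpec
        All mRNA species sharing the pool (include the monitor explicitly).
    p : ModelParams
    tol : float
        Absolute tolerance on the maximum occupancy time-derivative.
    method : {"auto", "root", "relax"}
        "root" solves ``rhs = 0`` algebraically from an all-zeros guess;
        "relax" integrates the ODEs to long times (the independent route);
        "auto" tries "root" and falls back to relaxation plus a final
        root polish if the algebraic solve fails or leaves the physical
        domain.

    Raises
    ------
    ConvergenceError
        If the residual cannot be brought below ``tol``.
    """
    if len(species) == 0:
        raise ValueError("need at least one species")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    dim = sum(1 + c.n_sites for c in species)
    y0 = np.zeros(dim)

    if method not in ("auto", "root", "relax"):
        raise ValueError(f"unknown method {method!r}")

    if method in ("auto", "root"):
        sol = root(lambda yy: rhs(yy, species, p), y0, method="hybr", tol=tol * 1e-3)
        y = sol.x
        ok = np.max(np.abs(rhs(y, species, p))) <= tol and _valid(y, species, p)
        if ok:
            return _result_from(y, species, p, "root")
        if method == "root":
            raise ConvergenceError(
                "algebraic steady-state solve did not converge",
                float(np.max(np.abs(rhs(y, species, p)))),
            )

    y = _relax(y0, species, p, tol)
    if method == "auto":
        # polish the relaxed point algebraically
        sol = root(lambda yy: rhs(yy, species, p), y, method="hybr", tol=tol * 1e-3)
        if np.max(np.abs(rhs(sol.x, species, p))) <= tol and _valid(sol.x, species, p):
            return _result_from(sol.x, species, p, "relax+polish")
    res = float(np.max(np.abs(rhs(y, species, p))))
    if res <= tol and _valid(y, species, p):
        return _result_from(y, species, p, "relax")
    raise ConvergenceError("steady-state relaxation did not converge", res)


def normalized_capacity(
    species_without_monitor: Sequence[ConstructSpec],
    p: ModelParams,
    tol: float = 1e-9,
    method: str = "auto",
) -> float:
    """Monitor production rate with competitors present over monitor alone.

    1.0 means the competitors impose no burden; values fall toward 0 as the
    competitors sequester more of the shared pool.
    """
    alone = solve_steady_state([p.monitor], p, tol=tol, method=method)
    if not species_without_monitor:
        return 1.0
    full = solve_steady_state([p.monitor, *species_without_monitor], p, tol=tol, method=method)
    return float(full.production_rates[0] / alone.production_rates[0])
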