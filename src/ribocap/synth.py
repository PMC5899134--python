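"""Ground-truth-known synthetic data for every pipeline stage.

Emulates the statistical structure of the assays, not their biochemistry:

* a construct library with known (gamma, RBS strength, length) whose true
  in vitro capacities are computed with the competitive translation model;
* lysate kinetic traces — saturating GFP accumulation whose maximal
  windowed production rate carries the capacity signal times multiplicative
  measurement noise;
* in vivo kinetic traces — sigmoidal growth (lag, exponential, stationary;
  log-OD is logistic, so the specific growth rate peaks at the curve's
  midpoint) with GFP accumulating proportionally to OD at a per-OD rate set
  by the construct's true in vivo capacity;
* per-condition true in vivo capacities linear in the in vitro value with
  condition-dependent slope (faster growth, steeper slope), optionally
  minus an additive metabolic penalty for "active pathway" cohorts.

A single seeded generator drives all randomness; a fixed seed reproduces
every output exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.special import expit

from .gamma import AssayConfig
from .model import ConstructSpec, normalized_capacity, solve_steady_state
from .plates import PlateTimeSeries, write_plate_csv

__all__ = [
    "Condition",
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_library",
    "generate_lysate_trace",
    "generate_invivo_trace",
    "generate_dataset",
    "MONITOR_ALONE",
]

#: sample label of the monitor-alone reference wells
MONITOR_ALONE = "monitor_alone"

#: lysate trace shape: logistic accumulation midpoint (h) and time scale (h)
LYSATE_T_MID = 2.0
LYSATE_TAU = 0.5
LYSATE_SPAN_H = 8.0
LYSATE_DT_H = 5.0 / 60.0
#: monitor-alone maximal lysate production rate, fluorescence units / h
LYSATE_REFERENCE_RATE = 2.0e4

#: in vivo trace shape
VIVO_T_MID = 4.0  # h, log-OD sigmoid midpoint (mid-exponential)
VIVO_RAMP_H = 1.0  # h, width of the growth-rate ramp
VIVO_SPAN_H = 10.0
VIVO_DT_H = 10.0 / 60.0
VIVO_OD0 = 0.05
#: unburdened per-OD GFP production rate, fluorescence / (h * OD)
VIVO_REFERENCE_RATE = 1.0e4


@dataclass(frozen=True)
class Condition:
    """One (strain, medium) growth condition with its calibration line."""

    label: str
    slope: float
    intercept: float
    growth_rate: float  # h^-1, unburdened maximal specific growth rate


DEFAULT_CONDITIONS = (
    Condition("slow", 0.4, 0.35, 0.35),
    Condition("reference", 0.7, 0.19, 0.69),
    Condition("fast", 0.95, 0.05, 1.1),
)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_constructs: int = 12
    gamma_range: tuple[float, float] = (0.1, 3.0)  # log-uniform, s^-1
    rbs_choices: tuple[float, ...] = (2.1, 2.6, 1.0, 0.5)
    length_range: tuple[int, int] = (300, 3000)  # bp
    noise_cv: float = 0.05
    n_replicates: int = 3
    conditions: tuple[Condition, ...] = DEFAULT_CONDITIONS
    metabolic_penalty: float = 0.0
    assay: AssayConfig = field(default_factory=AssayConfig)

    def __post_init__(self):
        if self.n_constructs < 1:
            raise ValueError("n_constructs must be >= 1")
        if self.gamma_range[0] <= 0 or self.gamma_range[1] < self.gamma_range[0]:
            raise ValueError("gamma_range must be positive and ordered")
        if self.length_range[0] < 30 or self.length_range[1] < self.length_range[0]:
            raise ValueError("length_range must be >= 30 bp and ordered")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class SyntheticTruth:
    """Everything the generator knows that an analyst would estimate."""

    constructs: list[ConstructSpec]
    in_vitro_capacity: np.ndarray  # noise-free, model-computed
    conditions: tuple[Condition, ...]
    in_vivo_capacity: dict[str, np.ndarray]  # per condition label
    metabolic_penalty: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "metabolic_penalty": self.metabolic_penalty,
            "constructs": [c.to_dict() for c in self.constructs],
            "in_vitro_capacity": self.in_vitro_capacity.tolist(),
            "conditions": [
                {
                    "label": c.label,
                    "slope": c.slope,
                    "intercept": c.intercept,
                    "growth_rate": c.growth_rate,
                }
                for c in self.conditions
            ],
            "in_vivo_capacity": {k: v.tolist() for k, v in self.in_vivo_capacity.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            constructs=[ConstructSpec.from_dict(c) for c in d["constructs"]],
            in_vitro_capacity=np.array(d["in_vitro_capacity"]),
            conditions=tuple(Condition(**c) for c in d["conditions"]),
            in_vivo_capacity={k: np.array(v) for k, v in d["in_vivo_capacity"].items()},
            metabolic_penalty=d["metabolic_penalty"],
            seed=d["seed"],
        )


def generate_library(cfg: GeneratorConfig) -> tuple[list[ConstructSpec], SyntheticTruth]:
    """Sample a construct library and compute its noise-free capacities."""
    rng = np.random.default_rng(cfg.seed)
    glo, ghi = cfg.gamma_range
    constructs = []
    for i in range(cfg.n_constructs):
        gamma = float(10 ** rng.uniform(np.log10(glo), np.log10(ghi)))
        rbs = float(rng.choice(cfg.rbs_choices))
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        constructs.append(
            ConstructSpec(
                name=f"g{i:02d}",
                rbs_strength=rbs,
                mrna_conc=cfg.assay.test_mrna_conc,
                length_bp=length,
                gamma=gamma,
            )
        )
    p = cfg.assay.model_params
    x = np.array([normalized_capacity([c], p) for c in constructs])
    in_vivo = {
        cond.label: cond.slope * x + cond.intercept - cfg.metabolic_penalty
        for cond in cfg.conditions
    }
    truth = SyntheticTruth(
        constructs=constructs,
        in_vitro_capacity=x,
        conditions=cfg.conditions,
        in_vivo_capacity=in_vivo,
        metabolic_penalty=cfg.metabolic_penalty,
        seed=cfg.seed,
    )
    return constructs, truth


def _amplitude_noise(rng: np.random.Generator, cv: float) -> float:
    """Mean-one multiplicative log-normal replicate noise."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return float(rng.lognormal(-0.5 * sigma**2, sigma))


def generate_lysate_trace(
    capacity_truth: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    well_id: str = "",
    sample: str = "",
) -> PlateTimeSeries:
    """Lysate GFP kinetics whose maximal windowed production rate equals
    ``capacity_truth * LYSATE_REFERENCE_RATE`` times multiplicative noise.

    The trace is a logistic accumulation (expression ramps up, then
    plateaus as the batch reaction exhausts itself), sampled every 5 min
    over 8 h, with the steepest 1-h window centred on the midpoint.
    """
    if capacity_truth < 0:
        raise ValueError("capacity_truth must be >= 0")
    t = np.arange(0.0, LYSATE_SPAN_H + 1e-9, LYSATE_DT_H)
    if capacity_truth == 0:
        gfp = np.zeros_like(t)
    else:
        # windowed (+/- 0.5 h) rate at the midpoint for a unit-amplitude curve
        window_gain = expit(0.5 / LYSATE_TAU) - expit(-0.5 / LYSATE_TAU)
        amplitude = capacity_truth * LYSATE_REFERENCE_RATE / window_gain
        gfp = amplitude * expit((t - LYSATE_T_MID) / LYSATE_TAU)
        gfp = gfp * _amplitude_noise(rng, cfg.noise_cv)
    return PlateTimeSeries(time=t, gfp=gfp, well_id=well_id, sample=sample)


def generate_invivo_trace(
    capacity_truth: float,
    growth_rate: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    well_id: str = "",
    sample: str = "",
    condition: str = "",
) -> PlateTimeSeries:
    """In vivo GFP/OD kinetics with known per-OD production rate.

    OD is exp(logistic): the specific growth rate ramps up to
    ``growth_rate`` at the mid-exponential time (4 h) and back down to
    stationary phase. GFP accumulates at
    ``capacity_truth * VIVO_REFERENCE_RATE * OD(t)`` per hour, so the
    per-OD production statistic at mid-exponential recovers the truth.
    Sampled every 10 min over 10 h.
    """
    if growth_rate <= 0:
        raise ValueError("growth_rate must be > 0")
    if capacity_truth < 0:
        raise ValueError("capacity_truth must be >= 0")
    t = np.arange(0.0, VIVO_SPAN_H + 1e-9, VIVO_DT_H)
    s = (t - VIVO_T_MID) / VIVO_RAMP_H
    log_od = np.log(VIVO_OD0) + 4.0 * growth_rate * VIVO_RAMP_H * expit(s)
    od = np.exp(log_od)
    rate = capacity_truth * VIVO_REFERENCE_RATE * od  # fluorescence / h
    gfp = np.concatenate([[0.0], cumulative_trapezoid(rate, t)])
    gfp = gfp * _amplitude_noise(rng, cfg.noise_cv)
    return PlateTimeSeries(
        time=t, gfp=gfp, od600=od, well_id=well_id, sample=sample, condition=condition
    )


def generate_dataset(cfg: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete demo dataset: lysate plate, one in vivo plate per
    condition, the construct covariate table, and the truth record.

    Every plate includes ``n_replicates`` monitor-alone reference wells
    (capacity 1.0) used for normalization, plus ``n_replicates`` wells per
    construct. Returns the paths written, keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    constructs, truth = generate_library(cfg)
    rng = np.random.default_rng(cfg.seed + 1)  # trace noise stream

    paths: dict[str, Path] = {}

    lysate_wells = []
    for r in range(cfg.n_replicates):
        lysate_wells.append(
            generate_lysate_trace(1.0, cfg, rng, well_id=f"REF{r}", sample=MONITOR_ALONE)
        )
    for i, c in enumerate(constructs):
        for r in range(cfg.n_replicates):
            lysate_wells.append(
                generate_lysate_trace(
                    truth.in_vitro_capacity[i], cfg, rng,
                    well_id=f"W{i:02d}R{r}", sample=c.name,
                )
            )
    paths["lysate_plate"] = out_dir / "lysate_plate.csv"
    write_plate_csv(lysate_wells, paths["lysate_plate"])

    for cond in cfg.conditions:
        wells = []
        for r in range(cfg.n_replicates):
            wells.append(
                generate_invivo_trace(
                    1.0, cond.growth_rate, cfg, rng,
                    well_id=f"REF{r}", sample=MONITOR_ALONE, condition=cond.label,
                )
            )
        for i, c in enumerate(constructs):
            cap = truth.in_vivo_capacity[cond.label][i]
            # burdened cells also grow more slowly, in proportion to capacity
            mu = cond.growth_rate * max(cap, 0.05)
            for r in range(cfg.n_replicates):
                wells.append(
                    generate_invivo_trace(
                        cap, mu, cfg, rng,
                        well_id=f"W{i:02d}R{r}", sample=c.name, condition=cond.label,
                    )
                )
        key = f"invivo_{cond.label}"
        paths[key] = out_dir / f"{key}.csv"
        write_plate_csv(wells, paths[key])

    paths["constructs"] = out_dir / "constructs.csv"
    pd.DataFrame(
        [
            {"sample": c.name, "rbs_strength": c.rbs_strength, "length_bp": c.length_bp}
            for c in constructs
        ]
    ).to_csv(paths["constructs"], index=False)

    paths["truth"] = out_dir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
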