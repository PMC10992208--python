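"""Seeded synthetic pretreatment/hydrolysis experiments.

Stands in for the study's raw 77-run experimental table.  The generator
produces a smooth, non-linear, noisy response over the standard design
space:

* a latent pretreatment severity combines the scaled acid term
  (concentration times an acid-strength multiplier, H2SO4 > HCl > H3PO4),
  temperature, residence time and (negatively) the solid-to-liquid ratio;
* glucose rises with severity through a concave ramp and saturates in the
  enzyme dose via a Michaelis-type factor E / (E + K_E);
* phenolics follow a logistic curve in severity alone (lignin breakdown
  products track pretreatment harshness, not the enzyme step);
* multiplicative Gaussian noise (coefficient of variation ``noise_cv``,
  z-score truncated at +/-2.5 sd) emulates between-replicate scatter, and
  the noiseless calibration bands sit inside the observed 7.5-25 g/L
  glucose and 0.8-3.0 g/L phenolics spans so noisy draws stay inside them.

Also provides the Folin-Ciocalteu forward model converting an absorbance
reading at 760 nm into total phenolic content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .dataset_io import (
    CANONICAL_SCHEMA,
    Dataset,
    DesignSpace,
    ExperimentRecord,
)

_CONTINUOUS_VARS = ("C_IA", "T", "t", "R_SL", "E")


@dataclass(frozen=True)
class GeneratorConfig:
    """Response-surface and noise parameters of the synthetic generator.

    ``severity_weights`` are the loadings (w1..w4) of the scaled acid term,
    temperature, time and solid-to-liquid ratio in the latent severity;
    ``acid_strength`` maps the acid code to its effective-strength
    multiplier.  Output bands are the *noiseless* spans in g/L, chosen
    strictly inside the observed measurement ranges so that noisy draws at
    the default CV remain inside them.
    """

    space: DesignSpace = field(default_factory=DesignSpace)
    severity_weights: tuple[float, float, float, float] = (0.45, 0.25, 0.10, 0.20)
    acid_strength: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.0, 2: 1.2, 3: 0.7}
    )
    K_E: float = 5.0  # FPU/g, half-saturation of the enzyme-dose factor
    glucose_band: tuple[float, float] = (8.6, 25.6)  # g/L; effective max 22.2
    phenolics_band: tuple[float, float] = (0.85, 3.0)  # g/L
    noise_cv: float = 0.05
    noise_z_max: float = 2.5  # truncation of the noise z-score, in sd units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.glucose_band[1] <= self.glucose_band[0] or self.phenolics_band[1] <= self.phenolics_band[0]:
            raise ValueError("output bands must have positive span")


def generate_design(space: DesignSpace, n_runs: int, seed: int) -> pd.DataFrame:
    """Seeded Latin-hypercube design over the continuous conditions.

    Continuous variables get space-filling coverage of their intervals;
    the acid code is assigned uniformly at random from the allowed set.
    Every row passes the design-space range check by construction.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=len(_CONTINUOUS_VARS), seed=rng)
    unit = sampler.random(n_runs)
    lows = np.array([space.interval(v)[0] for v in _CONTINUOUS_VARS])
    highs = np.array([space.interval(v)[1] for v in _CONTINUOUS_VARS])
    values = qmc.scale(unit, lows, highs)
    codes = rng.choice(space.acid_codes, size=n_runs)
    df = pd.DataFrame(values, columns=_CONTINUOUS_VARS)
    df.insert(0, "k_IA", codes.astype(int))
    df.insert(0, "run_id", [f"syn_{i + 1:03d}" for i in range(n_runs)])
    return df


def _unit(value: float, lo: float, hi: float) -> float:
    return (value - lo) / (hi - lo)


def severity(conditions: Mapping[str, float], cfg: GeneratorConfig) -> float:
    """Latent pretreatment severity s of one condition row (noise-free)."""
    sp = cfg.space
    k = int(conditions["k_IA"])
    if k not in cfg.acid_strength:
        raise ValueError(f"no acid-strength multiplier for code {k}")
    p = dict(cfg.acid_strength)
    acid_lo = sp.C_IA[0] * min(p.values())
    acid_hi = sp.C_IA[1] * max(p.values())
    w1, w2, w3, w4 = cfg.severity_weights
    return (
        w1 * _unit(conditions["C_IA"] * p[k], acid_lo, acid_hi)
        + w2 * _unit(conditions["T"], *sp.T)
        + w3 * _unit(conditions["t"], *sp.t)
        - w4 * _unit(conditions["R_SL"], *sp.R_SL)
    )


def noiseless_outputs(conditions: Mapping[str, float], cfg: GeneratorConfig) -> tuple[float, float]:
    """Noise-free (C_Glc, C_Phe) in g/L for one condition row."""
    s = severity(conditions, cfg)
    g_lo, g_hi = cfg.glucose_band
    p_lo, p_hi = cfg.phenolics_band
    ramp = math.sqrt(min(max(s, 0.0), 1.0))  # concave saturating ramp in severity
    enz = conditions["E"] / (conditions["E"] + cfg.K_E)
    c_glc = g_lo + (g_hi - g_lo) * ramp * enz
    c_phe = p_lo + (p_hi - p_lo) / (1.0 + math.exp(-4.0 * (s - 0.5)))
    return c_glc, c_phe


def _noisy(value: float, cfg: GeneratorConfig, rng: np.random.Generator) -> float:
    z = float(np.clip(rng.standard_normal(), -cfg.noise_z_max, cfg.noise_z_max))
    return max(value * (1.0 + cfg.noise_cv * z), 0.0)


def simulate_experiment(
    conditions: Mapping[str, float],
    cfg: GeneratorConfig,
    seed: int | np.random.Generator = 0,
    replicates: int = 1,
    run_id: str | None = None,
) -> ExperimentRecord:
    """Simulate one run (optionally as the mean of replicate measurements).

    ``conditions`` must carry k_IA, C_IA, T, t, R_SL and E inside the design
    space.  With ``noise_cv = 0`` the result is a deterministic function of
    the conditions regardless of the seed.
    """
    sp = cfg.space
    for var in _CONTINUOUS_VARS:
        lo, hi = sp.interval(var)
        if not lo <= float(conditions[var]) <= hi:
            raise ValueError(f"{var} = {conditions[var]} outside design space [{lo}, {hi}]")
    if int(conditions["k_IA"]) not in sp.acid_codes:
        raise ValueError(f"acid code {conditions['k_IA']} not allowed")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    base_glc, base_phe = noiseless_outputs(conditions, cfg)
    glc = float(np.mean([_noisy(base_glc, cfg, rng) for _ in range(replicates)]))
    phe = float(np.mean([_noisy(base_phe, cfg, rng) for _ in range(replicates)]))
    return ExperimentRecord(
        run_id=run_id or str(conditions.get("run_id", "syn_run")),
        k_IA=int(conditions["k_IA"]),
        C_IA=float(conditions["C_IA"]),
        T=float(conditions["T"]),
        t=float(conditions["t"]),
        R_SL=float(conditions["R_SL"]),
        E=float(conditions["E"]),
        C_Glc=glc,
        C_Phe=phe,
    )


def generate_dataset(
    cfg: GeneratorConfig,
    n_runs: int = 77,
    seed: int | None = None,
    replicates: int = 3,
) -> Dataset:
    """A full synthetic run table: design + simulated replicate-mean outputs."""
    seed = cfg.seed if seed is None else seed
    design = generate_design(cfg.space, n_runs, seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 77)).generate_state(1)[0])
    records = [
        simulate_experiment(row, cfg, seed=rng, replicates=replicates, run_id=row["run_id"])
        for row in design.to_dict("records")
    ]
    return Dataset(records, provenance="synthetic")


# ---------------------------------------------------------------------------
# Folin-Ciocalteu assay forward model


@dataclass(frozen=True)
class AssayParams:
    """Inputs of the total-phenolics colorimetric determination."""

    a: float  # linear coefficient of the gallic-acid standard curve
    A760: float  # absorbance of the reaction mixture at 760 nm
    V_s: float  # reaction-mixture volume, mL
    N: float = 1.0  # dilution ratio

    def __post_init__(self) -> None:
        if self.V_s <= 0:
            raise ValueError("reaction-mixture volume V_s must be > 0")
        if self.N < 1:
            raise ValueError("dilution ratio N must be >= 1")
        if self.A760 < 0:
            raise ValueError("absorbance A760 must be >= 0")


def phenolics_from_absorbance(p: AssayParams) -> float:
    """Total phenolic content in g/L: C_Phe = (a * A760 / V_s) * N."""
    return (p.a * p.A760 / p.V_s) * p.N
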