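"""Synthetic experiment oracle and packaged study fixtures.

Ground-truth response surfaces are the two published quadratic equations for
the co-milled composition (dissolved amount at pH 12 / 30 min and at
pH 1.2 + 0.2% SLS / 120 min), evaluated with optional Gaussian replicate
noise.  A one-compartment oral PK simulator supports the NCA code, and the
study's printed data tables ship verbatim as CSV fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .biometrics import PKProfile
from .design import DesignMatrix, ResponseTable
from .rsm import QuadraticModel

__all__ = [
    "EQ3_Y1",
    "EQ4_Y2",
    "BO_BOUNDS",
    "OracleConfig",
    "PKSimConfig",
    "true_response",
    "simulate_experiment",
    "generate_doe_dataset",
    "simulate_pk_profile",
    "load_fixture",
    "FIXTURE_NAMES",
]

# Published quadratic surface for Y1 (dissolved amount, pH 12, 30 min),
# actual-scale coefficients.
EQ3_Y1 = QuadraticModel(
    factor_names=("X1", "X2", "X3"),
    intercept=-7.3,
    linear=(-7.0, -157.8, 26.1),
    interaction=(250.5, 2.7, -105.0),
    quadratic=(12.8, 608.9, -1.7),
    scale="actual",
)

# Published quadratic surface for Y2 (dissolved amount, pH 1.2 + 0.2% SLS, 120 min).
EQ4_Y2 = QuadraticModel(
    factor_names=("X1", "X2", "X3"),
    intercept=-14.8,
    linear=(16.1, 1.8, 37.0),
    interaction=(188.2, 0.25, -4.3),
    quadratic=(-7.79, -309.2, -19.19),
    scale="actual",
)

_SURFACES = {"eq3_y1": EQ3_Y1, "eq4_y2": EQ4_Y2}

# Scan box used for the single-response optimization of Y2.
BO_BOUNDS = ((0.5, 2.0), (0.0, 0.2), (0.5, 2.0))

FIXTURE_NAMES = (
    "table1_levels",
    "table2_init",
    "table3_bo_proposals",
    "table4_ccd",
    "table5_anova_y1",
    "table6_validation",
    "table7_bo_results",
    "table9_pk",
    "invitro_comparisons",
)


@dataclass
class OracleConfig:
    """Ground-truth surface plus replicate-noise model for in-silico runs."""

    surface: str | QuadraticModel = "eq4_y2"
    noise_sd: float = 0.0
    bounds: tuple = BO_BOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.surface, str) and self.surface not in _SURFACES:
            raise KeyError(f"unknown surface {self.surface!r}; use {sorted(_SURFACES)} or a model")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be finite and >= 0")

    @property
    def model(self) -> QuadraticModel:
        return _SURFACES[self.surface] if isinstance(self.surface, str) else self.surface


def true_response(config: OracleConfig, x) -> float:
    """Noise-free surface value at x (global polynomial; out-of-box warns)."""
    x = np.asarray(x, dtype=float)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    if np.any(x < lo) or np.any(x > hi):
        import warnings

        warnings.warn("evaluation point outside oracle bounds; extrapolating the polynomial")
    return float(config.model.predict(x))


def _replicate_rng(seed: int, replicate_id: int, x: np.ndarray) -> np.ndarray:
    # counter-based stream: the key encodes (seed, replicate_id, bits of x)
    bits = np.asarray(x, dtype=np.float64).view(np.uint64)
    key = [np.uint64(seed & 0xFFFFFFFF), np.uint64(replicate_id)] + [b for b in bits]
    return np.random.default_rng(key)


def simulate_experiment(config: OracleConfig, x, replicate_id: int = 0) -> float:
    """true_response + N(0, noise_sd^2); reproducible from (seed, replicate_id, x)."""
    x = np.asarray(x, dtype=float)
    value = true_response(config, x)
    if config.noise_sd > 0:
        rng = _replicate_rng(config.seed, replicate_id, x)
        value += config.noise_sd * rng.standard_normal()
    return float(value)


def generate_doe_dataset(
    design: DesignMatrix,
    truth: QuadraticModel,
    noise_sd: float = 0.0,
    seed: int = 0,
    response_name: str = "Y",
) -> ResponseTable:
    """Simulated responses at every design run, for parameter-recovery tests."""
    X = design.actual_array() if truth.scale == "actual" else design.coded_array()
    y = truth.predict(X)
    if noise_sd > 0:
        y = y + noise_sd * np.random.default_rng(seed).standard_normal(len(y))
    codes = [p.code for p in design.points]
    return ResponseTable.from_arrays(codes, **{response_name: y})


@dataclass
class PKSimConfig:
    """One-compartment oral-absorption profile generator settings."""

    dose: float  # mg/kg
    ka: float  # 1/h
    ke: float  # 1/h
    volume_over_F: float  # L/kg
    sample_times: tuple  # h
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.ke <= 0 or self.volume_over_F <= 0:
            raise ValueError("ka, ke and volume_over_F must be > 0")
        if np.isclose(self.ka, self.ke):
            raise ValueError("ka must differ from ke (flip-flop degenerate case)")
        t = np.asarray(self.sample_times, dtype=float)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be non-negative and strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def simulate_pk_profile(config: PKSimConfig) -> PKProfile:
    """C(t) = D ka / (V/F (ka - ke)) (exp(-ke t) - exp(-ka t)), lognormal noise.

    The multiplicative noise has unit mean and coefficient of variation
    ``noise_cv``.  Concentrations come out in dose-units per L (mg/L == ug/mL
    for a mg/kg dose and L/kg volume).
    """
    t = np.asarray(config.sample_times, dtype=float)
    scale = config.dose * config.ka / (config.volume_over_F * (config.ka - config.ke))
    conc = scale * (np.exp(-config.ke * t) - np.exp(-config.ka * t))
    conc = np.maximum(conc, 0.0)
    if config.noise_cv > 0:
        rng = np.random.default_rng(config.seed)
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        conc = conc * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(t))
    return PKProfile(times=tuple(t), concentrations=tuple(conc), dose=config.dose)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged study table verbatim; see FIXTURE_NAMES for keys."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    path = resources.files("formuopt").joinpath("data", f"{name}.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def ccd_fixture_design() -> DesignMatrix:
    """The 20-run CCD reconstructed to match the packaged run table."""
    from .design import FactorSpec, generate_ccd

    factors = [
        FactorSpec("X1", center=1.0, half_range=0.5),
        FactorSpec("X2", center=0.1, half_range=0.1),
        FactorSpec("X3", center=1.0, half_range=0.5),
    ]
    return generate_ccd(factors, alpha=1.633, n_center_cube=4, n_center_axial=2)


def ccd_fixture_responses() -> tuple[DesignMatrix, ResponseTable]:
    """Packaged 20-run responses aligned onto the generated CCD geometry.

    The packaged run table's rows are matched to generated design points by
    factor settings (the historical run order differs from the generator's
    deterministic order); center replicates are assigned within block in
    row order.
    """
    design = ccd_fixture_design()
    table = load_fixture("table4_ccd")
    used = set()
    codes, y1, y2 = [], [], []
    for p in design.points:
        actual = np.round(p.actual_levels, 4)
        match = None
        for i, row in table.iterrows():
            if i in used:
                continue
            if np.allclose(np.round([row.X1, row.X2, row.X3], 4), actual, atol=5e-4):
                match = i
                break
        if match is None:
            raise ValueError(f"no fixture row for design point {p.code} at {actual}")
        used.add(match)
        codes.append(p.code)
        y1.append(float(table.loc[match, "Y1"]))
        y2.append(float(table.loc[match, "Y2"]))
    return design, ResponseTable.from_arrays(codes, Y1=y1, Y2=y2)
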