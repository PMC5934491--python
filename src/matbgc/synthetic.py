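"""Seeded generators for every input family of the pipeline.

No raw field measurements are published for this kind of study, so each
downstream stage is exercised against synthetic tables with known ground
truth: a descent/wall light log with a known sensor law, a longpass
filter sequence drawn from a known spectrum, ¹³C incubation vials with a
known per-cell uptake rate, whole-core ³⁵S tracer slices with a known
volumetric rate profile, and solid-phase slices with known pool
profiles.  Defaults mimic the magnitudes of a low-light mat below a
stratified sinkhole halocline: wall irradiance of a few times
10⁻² μmol photons m⁻² s⁻¹ dominated by UV and green bands, vial uptake
near 0.8 nmol C h⁻¹, sulfate reduction from undetectable to
~10² nmol cm⁻³ d⁻¹, and a pyrite-rich solid phase.

Noise model: multiplicative log-normal (unit mean) for sensor and
chemistry measurements, Poisson-like counting noise (normal
approximation, sd = √activity) for tracer activities.  Every generator
draws from its own RNG stream derived from ``(seed, generator id)``, so
adding a generator never perturbs another's draws; identical seed and
config give bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .carbon_uptake import (
    MOLAR_MASS_C,
    NATURAL_13C_RATIO,
    CellModel,
    LabelSpec,
    labeling_fraction,
    ratio_from_atom_fraction,
)
from .spectra import DEFAULT_CUTOFFS_NM, PiecewiseSpectrum

__all__ = [
    "PowerLawSensor",
    "ScenarioConfig",
    "LightLog",
    "FilterSequence",
    "IncubationSet",
    "TracerCores",
    "SolidPhase",
    "default_spectrum",
    "gen_light_log",
    "gen_filter_sequence",
    "gen_incubation",
    "gen_core_35s",
    "gen_solidphase",
]

# fixed per-generator stream ids (never reorder: reproducibility contract)
_STREAMS = {
    "light_log": 11,
    "filter_sequence": 12,
    "incubation": 13,
    "core_35s": 14,
    "solidphase": 15,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def _lognormal_factors(
    rng: np.random.Generator, rel_sd: float, size: int
) -> np.ndarray:
    """Unit-mean multiplicative noise factors with relative sd ``rel_sd``."""
    if rel_sd < 0:
        raise ValueError("noise sd must be non-negative")
    if rel_sd == 0:
        return np.ones(size)
    sigma2 = math.log1p(rel_sd**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


# ---------------------------------------------------------------------------
# sensor law and spectrum defaults


@dataclass(frozen=True)
class PowerLawSensor:
    """True signal↔irradiance law of the synthetic PMT logger.

    ``irradiance = amplitudes[gain] × signal ** exponent`` per gain
    level; higher gain levels have smaller amplitudes (more
    amplification).  The logger switches to the highest gain whose
    signal stays below ``signal_max``.
    """

    amplitudes: tuple[float, ...] = (1.0, 1e-2, 1e-4)
    exponent: float = 1.0
    signal_max: float = 1e4

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError("non-monotone sensor law: exponent must be > 0")
        if any(a <= 0 for a in self.amplitudes):
            raise ValueError("non-monotone sensor law: amplitudes must be > 0")
        if self.signal_max <= 0:
            raise ValueError("signal_max must be positive")

    def signal(self, irradiance: float, gain: int) -> float:
        return (irradiance / self.amplitudes[gain]) ** (1.0 / self.exponent)

    def select_gain(self, irradiance: float) -> int:
        for gain in range(len(self.amplitudes) - 1, -1, -1):
            if self.signal(irradiance, gain) <= self.signal_max:
                return gain
        return 0


def default_spectrum(total: float = 0.084) -> PiecewiseSpectrum:
    """UV-dominated wall spectrum: 64% below 400 nm, a secondary green
    maximum (21% at 475–530 nm), nothing above 590 nm."""
    return PiecewiseSpectrum.from_band_fractions(
        {
            (320.0, 400.0): 0.64,
            (400.0, 475.0): 0.06,
            (475.0, 530.0): 0.21,
            (530.0, 590.0): 0.09,
            (590.0, 700.0): 0.0,
        },
        total=total,
    )


def _default_pool_profiles() -> dict[str, tuple[tuple[float, float], ...]]:
    # piecewise-linear (depth cm, value) node lists
    return {
        "avs": ((0.0, 0.05), (4.2, 0.05)),  # μmol S cm⁻³, almost absent
        "crs": ((0.0, 2.0), (4.2, 44.0)),  # μmol S cm⁻³, pyrite-rich at depth
        "s0": ((0.0, 0.12), (0.25, 0.12), (0.5, 0.02), (4.2, 0.02)),
        "dith_fe": ((0.0, 12.0), (4.2, 12.0)),  # μmol Fe cm⁻³
        "so4_porewater": ((0.0, 28000.0), (4.2, 28000.0)),  # μmol L⁻¹
    }


def _profile_mean(
    nodes: tuple[tuple[float, float], ...], top: float, bottom: float
) -> float:
    """Exact average of a piecewise-linear profile over [top, bottom]."""
    xs = np.array([p[0] for p in nodes], dtype=float)
    ys = np.array([p[1] for p in nodes], dtype=float)
    inner = xs[(xs > top) & (xs < bottom)]
    grid = np.concatenate(([top], inner, [bottom]))
    vals = np.interp(grid, xs, ys)
    return float(np.trapezoid(vals, grid) / (bottom - top))


# ---------------------------------------------------------------------------
# configuration


def _default_noise() -> dict[str, float]:
    return {
        "par": 0.02,  # PAR sensor reading, relative sd
        "signal": 0.02,  # PMT raw signal
        "filter": 0.02,  # filter-wheel readings
        "ratio": 0.005,  # isotope ratio measurements
        "total_c": 0.03,  # filter carbon mass
        "solid": 0.05,  # solid-phase and sulfate chemistry
    }


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground truth plus noise levels for one synthetic field campaign.

    All measurement-noise magnitudes live in ``noise`` (relative sd per
    measurement family; instruments' true error magnitudes are unknown,
    so these are deliberate, config-exposed choices).  Tracer counting
    noise is controlled by ``tracer_noise``: ``"poisson"`` for
    sd = √activity, a float for a relative sd, ``0`` for none.
    """

    seed: int = 0

    # --- light field ---
    spectrum: PiecewiseSpectrum = field(default_factory=default_spectrum)
    sensor: PowerLawSensor = field(default_factory=PowerLawSensor)
    par_floor: float = 0.1  # μmol m⁻² s⁻¹, PAR sensitivity floor
    surface_irradiance: float = 500.0
    attenuation_breaks: tuple[float, ...] = (17.0, 25.0, 27.0)
    attenuation_ks: tuple[float, ...] = (0.18, 0.28, 0.8)  # m⁻¹ per segment
    center_irradiance_30m: float = 0.27  # anchors the deepest segment
    descent_rate: float = 4.3 / 60.0  # m s⁻¹
    max_depth: float = 40.0
    wall_depth: float = 30.0
    wall_duration_s: float = 7200.0
    wall_interval_s: float = 10.0
    wall_peak: float = 0.084
    wall_decline: float = 0.15  # clear-sky fractional decline over the series
    cloud_min_factor: float = 0.3
    n_clouds: int = 5
    filter_cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS_NM
    filter_transmission: float = 0.90

    # --- carbon uptake ---
    true_per_cell_rate: float = 7.155e-9  # nmol C cell⁻¹ h⁻¹ (DIC, light)
    true_per_cell_rate_acetate: float = 1.2e-10
    dark_fraction: float = 0.08  # dark rate as a fraction of the light rate
    cells_per_vial: float = 1.16e8
    blank_carbon_ug: float = 2.0
    cell_model: CellModel = field(default_factory=CellModel)
    label_dic: LabelSpec = field(
        default_factory=lambda: LabelSpec(
            substrate="DIC", label_added=73.8, labeled_positions=1,
            total_positions=1, ambient_conc=104.8, vial_volume=6.0,
        )
    )
    label_acetate: LabelSpec = field(
        default_factory=lambda: LabelSpec(
            substrate="acetate", label_added=73.8, labeled_positions=1,
            total_positions=2, ambient_conc=0.0, vial_volume=6.0,
        )
    )
    timepoints_h: tuple[float, ...] = (24.0, 60.0)  # recovery, natural-light h
    n_replicates: int = 3
    natural_ratio: float = NATURAL_13C_RATIO

    # --- sulfate reduction ---
    n_cores: int = 10
    core_length: float = 4.2  # cm
    tracer_slice_thickness: float = 0.6  # cm
    core_radius: float = 1.0  # cm
    injected_activity_dpm_cm3: float = 1.98e6  # ~33 kBq cm⁻³
    incubation_days: tuple[float, ...] = (4 / 24, 4 / 24, 4 / 24, 4 / 24,
                                          4 / 24, 4 / 24, 0.25, 0.25, 0.25,
                                          0.25)
    fractionation: float = 1.06
    true_srr_profile: tuple[tuple[float, float], ...] | None = None
    srr_base_median: float = 0.8  # nmol cm⁻³ d⁻¹, lognormal median
    srr_base_sigma: float = 1.0  # lognormal shape of the quiet background
    srr_hot_range: tuple[float, float] = (10.0, 99.2)  # hot-spot rates
    srr_hot_mean_per_core: float = 1.0  # Poisson mean number of hot slices
    blank_dpm_mean: float = 30.5
    blank_dpm_sd: float = 8.0
    n_blanks: int = 5
    tracer_noise: str | float = "poisson"

    # --- solid phase ---
    pool_profiles: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=_default_pool_profiles
    )
    slice_thickness: float = 0.25  # cm
    solid_core_length: float = 4.0  # cm
    porosity: float = 0.92
    wet_density: float = 1.11

    # --- noise ---
    noise: dict[str, float] = field(default_factory=_default_noise)

    def with_noise(self, **levels: float) -> "ScenarioConfig":
        """Copy with some noise families overridden (e.g. all set to 0)."""
        return replace(self, noise={**self.noise, **levels})

    def noiseless(self) -> "ScenarioConfig":
        zero = {k: 0.0 for k in self.noise}
        return replace(self, noise=zero, tracer_noise=0.0, blank_dpm_sd=0.0)


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class LightLog:
    samples: pd.DataFrame  # time, depth, par, signal, gain, phase
    truth: pd.DataFrame  # time, depth, irradiance, phase


@dataclass(frozen=True)
class FilterSequence:
    steps: pd.DataFrame  # cutoff (NaN = unfiltered), reading, transmission
    truth: pd.DataFrame  # band, irradiance, fraction
    spectrum: PiecewiseSpectrum


@dataclass(frozen=True)
class IncubationSet:
    samples: pd.DataFrame  # treatment, condition, light_hours, ratio, total_c
    truth: dict


@dataclass(frozen=True)
class TracerCores:
    samples: pd.DataFrame  # core, depths, a_tris, a_so4, so4_conc, time, volume
    blanks: pd.DataFrame  # blank dpm values
    truth: pd.DataFrame  # core, depths, rate


@dataclass(frozen=True)
class SolidPhase:
    samples: pd.DataFrame  # depths + avs, crs, s0, dith_fe, so4_porewater
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# light log


def _true_irradiance_at_depth(cfg: ScenarioConfig, depth: np.ndarray) -> np.ndarray:
    """Piecewise-exponential depth attenuation, anchored so that the
    irradiance at 30 m in the cave center equals ``center_irradiance_30m``."""
    breaks = np.array((0.0,) + cfg.attenuation_breaks)
    ks = np.array(cfg.attenuation_ks)
    # optical depth accumulated at each break
    seg_od = ks * np.diff(breaks)
    od_at_break = np.concatenate(([0.0], np.cumsum(seg_od)))
    e_deep_top = cfg.surface_irradiance * math.exp(-od_at_break[-1])
    deep_top = breaks[-1]
    if cfg.wall_depth <= deep_top or e_deep_top <= cfg.center_irradiance_30m:
        raise ValueError("attenuation profile inconsistent with the 30 m anchor")
    k_deep = math.log(e_deep_top / cfg.center_irradiance_30m) / (
        cfg.wall_depth - deep_top
    )

    depth = np.asarray(depth, dtype=float)
    od = np.empty_like(depth)
    for i, z in enumerate(depth):
        j = np.searchsorted(breaks, z, side="right") - 1
        j = min(j, len(ks))  # beyond last break -> deep segment
        if j >= len(ks):
            od[i] = od_at_break[-1] + k_deep * (z - deep_top)
        else:
            od[i] = od_at_break[j] + ks[j] * (z - breaks[j])
    return cfg.surface_irradiance * np.exp(-od)


def _wall_series(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Clear-sky decline modulated by occasional cloud dips.

    The cloud factor is floored at ``cloud_min_factor`` and the clear
    sky declines by ``wall_decline``, bounding the series inside
    ``[wall_peak × (1 − decline) × floor, wall_peak]``.
    """
    t = np.arange(0.0, cfg.wall_duration_s + 1e-9, cfg.wall_interval_s)
    clear = cfg.wall_peak * (1.0 - cfg.wall_decline * t / cfg.wall_duration_s)
    factor = np.ones_like(t)
    centers = rng.uniform(300.0, cfg.wall_duration_s - 300.0, cfg.n_clouds)
    widths = rng.uniform(60.0, 300.0, cfg.n_clouds)
    amps = rng.uniform(0.2, 0.75, cfg.n_clouds)
    for c, w, a in zip(centers, widths, amps):
        factor -= a * np.exp(-(((t - c) / w) ** 2))
    factor = np.clip(factor, cfg.cloud_min_factor, 1.0)
    return clear * factor


def gen_light_log(config: ScenarioConfig) -> LightLog:
    """Descent log through the water column plus a 2 h wall mooring.

    The descent covers the overlap zone where both the PAR sensor and
    the PMT are in range (PAR readings are masked below the sensor's
    floor); the wall phase sits at the mat depth where only the PMT
    responds.  Raw signals follow the configured sensor law with the
    logger's automatic gain selection.
    """
    rng = _rng(config.seed, "light_log")
    law = config.sensor  # validates monotonicity on construction

    # descent phase
    t_desc = np.arange(0.0, config.max_depth / config.descent_rate + 1e-9, 1.0)
    z_desc = np.minimum(t_desc * config.descent_rate, config.max_depth)
    e_desc = _true_irradiance_at_depth(config, z_desc)

    # wall phase
    e_wall = _wall_series(config, rng)
    t_wall = t_desc[-1] + 60.0 + np.arange(e_wall.size) * config.wall_interval_s
    z_wall = np.full(e_wall.size, config.wall_depth)

    time = np.concatenate([t_desc, t_wall])
    depth = np.concatenate([z_desc, z_wall])
    irr = np.concatenate([e_desc, e_wall])
    phase = np.array(["descent"] * t_desc.size + ["wall"] * t_wall.size)

    gain = np.array([law.select_gain(e) for e in irr])
    signal_true = np.array([law.signal(e, g) for e, g in zip(irr, gain)])
    signal = signal_true * _lognormal_factors(
        rng, config.noise["signal"], irr.size
    )
    par = irr * _lognormal_factors(rng, config.noise["par"], irr.size)
    par[irr < config.par_floor] = np.nan

    samples = pd.DataFrame(
        {
            "time": time,
            "depth": depth,
            "par": par,
            "signal": signal,
            "gain": gain,
            "phase": phase,
        }
    )
    truth = pd.DataFrame(
        {"time": time, "depth": depth, "irradiance": irr, "phase": phase}
    )
    return LightLog(samples=samples, truth=truth)


# ---------------------------------------------------------------------------
# filter sequence


def gen_filter_sequence(config: ScenarioConfig) -> FilterSequence:
    """Filter-wheel sequence: unfiltered reading then each longpass step.

    The unfiltered reading integrates the whole spectrum; a filter with
    cutoff λc reads ``transmission × ∫_{λc} spectrum``.  Multiplicative
    noise is applied per reading.
    """
    rng = _rng(config.seed, "filter_sequence")
    cutoffs = np.asarray(config.filter_cutoffs, dtype=float)
    if np.any(np.diff(cutoffs) <= 0):
        raise ValueError("filter cutoffs must be strictly increasing")
    spectrum = config.spectrum

    readings_true = np.concatenate(
        (
            [spectrum.total()],
            [
                config.filter_transmission * spectrum.integral_above(c)
                for c in cutoffs
            ],
        )
    )
    readings = readings_true * _lognormal_factors(
        rng, config.noise["filter"], readings_true.size
    )
    steps = pd.DataFrame(
        {
            "cutoff": np.concatenate(([np.nan], cutoffs)),
            "reading": readings,
            "transmission": np.concatenate(
                ([1.0], np.full(cutoffs.size, config.filter_transmission))
            ),
        }
    )
    bands = spectrum.band_irradiances(tuple(cutoffs))
    labels = [f"<{cutoffs[0]:g}"]
    labels += [f"{lo:g}-{hi:g}" for lo, hi in zip(cutoffs[:-1], cutoffs[1:])]
    labels += [f">{cutoffs[-1]:g}"]
    truth = pd.DataFrame(
        {
            "band": labels,
            "irradiance": bands,
            "fraction": bands / spectrum.total(),
        }
    )
    return FilterSequence(steps=steps, truth=truth, spectrum=spectrum)


# ---------------------------------------------------------------------------
# incubation vials


def gen_incubation(config: ScenarioConfig) -> IncubationSet:
    """¹³C incubation table for the DIC and acetate treatments.

    Emits natural-abundance triplicates (no label), t = 0 triplicates
    (label added, preserved immediately) and light/dark triplicates at
    each recovery time.  Excess ¹³C grows linearly: per vial and hour
    the true rate × labeling fraction nmol of ¹³C accumulate; dark
    vials run at ``dark_fraction`` of the light rate.
    """
    for name, sd in config.noise.items():
        if sd < 0:
            raise ValueError(f"negative noise sd for family {name!r}")
    if config.true_per_cell_rate < 0 or config.true_per_cell_rate_acetate < 0:
        raise ValueError("true per-cell rates must be non-negative")

    rng = _rng(config.seed, "incubation")
    cpc = config.cell_model.carbon_per_cell_fg
    total_c_true = config.cells_per_vial * cpc * 1e-9 + config.blank_carbon_ug
    total_nmol_true = total_c_true / MOLAR_MASS_C * 1e3
    x_na = config.natural_ratio / (1.0 + config.natural_ratio)

    treatments = {
        "DIC": (config.true_per_cell_rate, config.label_dic),
        "acetate": (config.true_per_cell_rate_acetate, config.label_acetate),
    }

    rows: list[dict] = []
    truth: dict = {"blank_carbon_ug": config.blank_carbon_ug}
    for treatment, (cell_rate, spec) in treatments.items():
        frac = labeling_fraction(spec)
        vial_rate = cell_rate * config.cells_per_vial  # nmol C vial⁻¹ h⁻¹
        truth[treatment] = {
            "labeling_fraction": frac,
            "true_vial_rate_light": vial_rate,
            "true_vial_rate_dark": vial_rate * config.dark_fraction,
            "true_per_cell_rate": cell_rate,
            "cells_per_vial": config.cells_per_vial,
            "total_c_ug": total_c_true,
        }
        schedule = [("natural_abundance", None, None)]
        schedule += [("t0", 0.0, None)]
        for t in config.timepoints_h:
            schedule += [("light", t, 1.0), ("dark", t, config.dark_fraction)]
        for condition, hours, rate_scale in schedule:
            for _ in range(config.n_replicates):
                if condition == "natural_abundance":
                    x = x_na
                    hours_out = np.nan
                else:
                    excess = (
                        vial_rate * (rate_scale or 1.0) * frac * (hours or 0.0)
                    )
                    x = x_na + excess / total_nmol_true
                    hours_out = hours
                ratio = ratio_from_atom_fraction(x)
                ratio *= _lognormal_factors(rng, config.noise["ratio"], 1)[0]
                tc = (
                    total_c_true
                    * _lognormal_factors(rng, config.noise["total_c"], 1)[0]
                )
                rows.append(
                    {
                        "treatment": treatment,
                        "condition": condition,
                        "light_hours": hours_out,
                        "ratio_13c_12c": ratio,
                        "total_c": tc,
                    }
                )
    return IncubationSet(samples=pd.DataFrame(rows), truth=truth)


# ---------------------------------------------------------------------------
# 35S tracer cores


def _true_srr_for_core(
    config: ScenarioConfig,
    rng: np.random.Generator,
    mids: np.ndarray,
) -> np.ndarray:
    if config.true_srr_profile is not None:
        xs = np.array([p[0] for p in config.true_srr_profile])
        ys = np.array([p[1] for p in config.true_srr_profile])
        return np.interp(mids, xs, ys)
    base = rng.lognormal(
        mean=math.log(config.srr_base_median),
        sigma=config.srr_base_sigma,
        size=mids.size,
    )
    n_hot = rng.poisson(config.srr_hot_mean_per_core)
    if n_hot > 0:
        idx = rng.choice(mids.size, size=min(n_hot, mids.size), replace=False)
        base[idx] = rng.uniform(*config.srr_hot_range, size=idx.size)
    return base


def gen_core_35s(config: ScenarioConfig) -> TracerCores:
    """³⁵S whole-core tracer slices for ``n_cores`` replicate cores.

    Per slice the injected activity partitions between residual sulfate
    and reduced sulfur according to the turnover fraction implied by
    the true rate, the sulfate pool, the fractionation factor and the
    incubation time.  Counting noise follows ``tracer_noise``.  Process
    blanks are drawn around ``blank_dpm_mean``.
    """
    if config.injected_activity_dpm_cm3 <= 0:
        raise ValueError("injected activity must be positive")
    if any(t <= 0 for t in config.incubation_days):
        raise ValueError("incubation times must be positive")
    if len(config.incubation_days) < config.n_cores:
        raise ValueError("need one incubation time per core")

    rng = _rng(config.seed, "core_35s")
    n_slices = int(round(config.core_length / config.tracer_slice_thickness))
    edges = np.arange(n_slices + 1) * config.tracer_slice_thickness
    mids = (edges[:-1] + edges[1:]) / 2.0
    area = math.pi * config.core_radius**2
    slice_vol = area * config.tracer_slice_thickness
    a_total = config.injected_activity_dpm_cm3 * slice_vol

    so4_nodes = config.pool_profiles["so4_porewater"]
    so4_true = np.array(
        [
            _profile_mean(so4_nodes, t, b) * config.porosity
            for t, b in zip(edges[:-1], edges[1:])
        ]
    )  # nmol S cm⁻³ whole mat

    sample_rows = []
    truth_rows = []
    for core in range(config.n_cores):
        t_inc = config.incubation_days[core]
        rates = _true_srr_for_core(config, rng, mids)
        turnover = rates * t_inc / (so4_true * config.fractionation)
        if np.any(turnover >= 1.0):
            raise ValueError(
                "true SRR implies > 100% tracer turnover; shorten the "
                "incubation or lower the rate"
            )
        if np.any(turnover > 0.05):
            import warnings

            warnings.warn(
                "tracer turnover above 5%; rate linearity degrades",
                stacklevel=2,
            )
        a_tris_true = turnover * a_total
        a_so4_true = (1.0 - turnover) * a_total
        if config.tracer_noise == "poisson":
            a_tris = rng.normal(a_tris_true, np.sqrt(a_tris_true))
            a_so4 = rng.normal(a_so4_true, np.sqrt(a_so4_true))
        elif float(config.tracer_noise) == 0.0:
            a_tris, a_so4 = a_tris_true.copy(), a_so4_true.copy()
        else:
            rel = float(config.tracer_noise)
            if rel < 0:
                raise ValueError("tracer noise must be non-negative")
            a_tris = a_tris_true * _lognormal_factors(rng, rel, mids.size)
            a_so4 = a_so4_true * _lognormal_factors(rng, rel, mids.size)
        a_tris = np.clip(a_tris, 0.0, None)
        a_so4 = np.clip(a_so4, 0.0, None)
        so4_meas = so4_true * _lognormal_factors(
            rng, config.noise["solid"], mids.size
        )
        for i in range(mids.size):
            sample_rows.append(
                {
                    "core": core,
                    "depth_top": edges[i],
                    "depth_bottom": edges[i + 1],
                    "a_tris": a_tris[i],
                    "a_so4": a_so4[i],
                    "so4_conc": so4_meas[i],
                    "time": t_inc,
                    "volume": slice_vol,
                }
            )
            truth_rows.append(
                {
                    "core": core,
                    "depth_top": edges[i],
                    "depth_bottom": edges[i + 1],
                    "rate": rates[i],
                    "turnover": turnover[i],
                }
            )
    blanks = rng.normal(
        config.blank_dpm_mean, config.blank_dpm_sd, config.n_blanks
    )
    blanks = np.clip(blanks, 0.0, None)
    return TracerCores(
        samples=pd.DataFrame(sample_rows),
        blanks=pd.DataFrame({"blank": blanks}),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# solid phase


def gen_solidphase(config: ScenarioConfig) -> SolidPhase:
    """Solid-phase slice table from the configured pool profiles.

    Slice values are the exact piecewise-linear profile averages over
    each slice, degraded by multiplicative noise.  The truth must
    satisfy CRS ≥ S⁰ everywhere (pyrite sulfur cannot be negative).
    """
    rng = _rng(config.seed, "solidphase")
    profiles = config.pool_profiles
    for name, nodes in profiles.items():
        if any(v < 0 for _, v in nodes):
            raise ValueError(f"profile {name!r} has negative values")
    n_slices = int(round(config.solid_core_length / config.slice_thickness))
    edges = np.arange(n_slices + 1) * config.slice_thickness

    truth_cols = {"depth_top": edges[:-1], "depth_bottom": edges[1:]}
    for analyte in ("avs", "crs", "s0", "dith_fe", "so4_porewater"):
        truth_cols[analyte] = np.array(
            [
                _profile_mean(profiles[analyte], t, b)
                for t, b in zip(edges[:-1], edges[1:])
            ]
        )
    truth = pd.DataFrame(truth_cols)
    if np.any(truth["crs"] < truth["s0"]):
        raise ValueError("true CRS profile below S0 profile somewhere")

    samples = truth.copy()
    for analyte in ("avs", "crs", "s0", "dith_fe", "so4_porewater"):
        samples[analyte] = truth[analyte] * _lognormal_factors(
            rng, config.noise["solid"], n_slices
        )
    return SolidPhase(samples=samples, truth=truth)
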