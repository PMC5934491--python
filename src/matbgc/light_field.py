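"""Irradiance calibration and longpass-filter spectral decomposition.

Two instruments measure downwelling light during a descent through the
water column: a cosine-corrected PAR sensor with an internal absolute
calibration, and a far more sensitive photomultiplier (PMT) logger whose
gain is switched by the diver to track ambient intensity.  Where both
sensors are in range, their paired readings define a per-gain
calibration curve that extends absolute irradiance down to the
10⁻² μmol photons m⁻² s⁻¹ light levels at the mat wall.

A filter wheel of longpass filters in front of the sensor yields
cumulative readings (everything above each cutoff, attenuated by a known
transmission).  Successive differences of the transmission-corrected
readings recover coarse wavelength-band irradiances and their fractional
share of the total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationError",
    "CalibrationCurve",
    "FilterStep",
    "SpectralBands",
    "fit_calibration",
    "apply_calibration",
    "decompose_longpass",
]


class CalibrationError(ValueError):
    """Raised when the sensor-overlap data cannot support a calibration."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-gain power-law mapping raw PMT signal → irradiance.

    For gain level ``g``: irradiance = ``a[g] × signal**b[g]`` with
    ``b[g] > 0``, hence strictly increasing in signal.  ``diagnostics``
    records per gain the number of overlap points used and the residual
    spread of the log-log fit.
    """

    params: dict[int, tuple[float, float]]  # gain -> (a, b)
    diagnostics: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gain, (a, b) in self.params.items():
            if a <= 0 or b <= 0:
                raise CalibrationError(
                    f"gain level {gain}: non-monotone mapping (a={a}, b={b})"
                )

    def predict(self, signal: np.ndarray, gain: np.ndarray) -> np.ndarray:
        """Irradiance for raw signals at given gain levels."""
        signal = np.asarray(signal, dtype=float)
        gain = np.asarray(gain)
        out = np.empty(signal.shape, dtype=float)
        for g in np.unique(gain):
            if int(g) not in self.params:
                raise CalibrationError(f"unknown gain level {int(g)} in samples")
            a, b = self.params[int(g)]
            mask = gain == g
            out[mask] = a * signal[mask] ** b
        return out


@dataclass(frozen=True)
class FilterStep:
    """One filter-wheel position: reading with everything above ``cutoff``.

    ``cutoff`` is None for the unfiltered reference reading.  The filter
    attenuates the passed light by a known factor, so the true
    above-cutoff irradiance is ``reading / transmission``.
    """

    cutoff: float | None
    reading: float
    transmission: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.transmission <= 1:
            raise ValueError("transmission must be in (0, 1]")
        if self.reading < 0:
            raise ValueError("reading must be non-negative")


@dataclass(frozen=True)
class SpectralBands:
    """Band irradiances derived from a longpass sequence.

    ``labels`` name the bands (``<400``, ``400-475``, …, ``>645``),
    ``irradiance`` is per-band μmol photons m⁻² s⁻¹ (clamped at 0),
    ``fraction`` their share of the unfiltered total (renormalized to
    sum to 1).  ``clamped`` flags that noise pushed at least one raw
    band negative before clamping.
    """

    labels: tuple[str, ...]
    edges: tuple[float, ...]
    irradiance: np.ndarray
    fraction: np.ndarray
    total: float
    clamped: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band": list(self.labels),
                "irradiance": self.irradiance,
                "fraction": self.fraction,
            }
        )

    def fraction_of(self, lo: float | None, hi: float | None) -> float:
        """Fraction of one band identified by its edges (None = open end)."""
        lo_s = "<" if lo is None else f"{lo:g}"
        hi_s = ">" if hi is None else f"{hi:g}"
        if lo is None:
            label = f"<{hi_s}"
        elif hi is None:
            label = f">{lo_s}"
        else:
            label = f"{lo_s}-{hi_s}"
        try:
            idx = self.labels.index(label)
        except ValueError as exc:
            raise KeyError(f"no band {label!r}; have {self.labels}") from exc
        return float(self.fraction[idx])


# ---------------------------------------------------------------------------
# calibration


def fit_calibration(samples: pd.DataFrame, min_points: int = 3) -> CalibrationCurve:
    """Fit the per-gain power-law calibration from sensor-overlap rows.

    ``samples`` needs columns ``par``, ``signal`` and ``gain``; rows
    where the PAR value is missing (below the PAR sensor's range) are
    ignored.  For every gain level appearing in ``samples``, at least
    ``min_points`` overlap rows are required; log(par) is regressed on
    log(signal) by least squares.
    """
    required = {"par", "signal", "gain"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples missing columns: {sorted(missing)}")

    params: dict[int, tuple[float, float]] = {}
    diagnostics: dict[int, dict[str, float]] = {}
    for g, group in samples.groupby("gain"):
        overlap = group.dropna(subset=["par"])
        overlap = overlap[(overlap["par"] > 0) & (overlap["signal"] > 0)]
        if len(overlap) < min_points:
            raise CalibrationError(
                f"gain level {int(g)}: only {len(overlap)} overlap samples "
                f"with valid PAR readings (need >= {min_points})"
            )
        log_s = np.log(overlap["signal"].to_numpy(dtype=float))
        log_p = np.log(overlap["par"].to_numpy(dtype=float))
        b, log_a = np.polyfit(log_s, log_p, 1)
        if b <= 0:
            raise CalibrationError(
                f"gain level {int(g)}: fitted mapping is not increasing (b={b:.3g})"
            )
        resid = log_p - (b * log_s + log_a)
        params[int(g)] = (float(np.exp(log_a)), float(b))
        diagnostics[int(g)] = {
            "n": float(len(overlap)),
            "resid_sd_log": float(np.std(resid, ddof=min(2, len(overlap) - 1))),
        }
    curve = CalibrationCurve(params=params, diagnostics=diagnostics)
    _assert_monotone(curve)
    return curve


def _assert_monotone(curve: CalibrationCurve, n_probe: int = 256) -> None:
    """Check strict monotonicity on a dense probe grid (cheap safeguard)."""
    probe = np.logspace(-3, 6, n_probe)
    for g in curve.params:
        pred = curve.predict(probe, np.full(n_probe, g))
        if np.any(np.diff(pred) <= 0):
            raise CalibrationError(f"gain level {g}: calibration not increasing")


def apply_calibration(curve: CalibrationCurve, samples: pd.DataFrame) -> pd.Series:
    """Calibrated irradiance (μmol photons m⁻² s⁻¹) for every sample row."""
    if "signal" not in samples or "gain" not in samples:
        raise ValueError("samples need 'signal' and 'gain' columns")
    irr = curve.predict(
        samples["signal"].to_numpy(dtype=float), samples["gain"].to_numpy()
    )
    return pd.Series(irr, index=samples.index, name="irradiance")


# ---------------------------------------------------------------------------
# longpass decomposition


def _band_labels(cutoffs: np.ndarray) -> tuple[str, ...]:
    labels = [f"<{cutoffs[0]:g}"]
    labels += [f"{lo:g}-{hi:g}" for lo, hi in zip(cutoffs[:-1], cutoffs[1:])]
    labels.append(f">{cutoffs[-1]:g}")
    return tuple(labels)


def decompose_longpass(
    steps: list[FilterStep] | pd.DataFrame,
    excess_tolerance: float = 1e-9,
) -> SpectralBands:
    """Recover band irradiances from a cumulative longpass sequence.

    Each filtered reading divided by its transmission estimates the
    irradiance above that cutoff; differences between successive
    above-cutoff values give the in-between bands, and the unfiltered
    reading minus the lowest-cutoff value gives the band below the first
    cutoff.  Measurement noise can make the cumulative sequence
    non-monotone; negative bands are clamped to zero and the fractions
    renormalized to sum to one (``clamped`` records that this happened).
    """
    if isinstance(steps, pd.DataFrame):
        steps = [
            FilterStep(
                cutoff=None if pd.isna(row["cutoff"]) else float(row["cutoff"]),
                reading=float(row["reading"]),
                transmission=float(row.get("transmission", 0.90)),
            )
            for _, row in steps.iterrows()
        ]

    unfiltered = [s for s in steps if s.cutoff is None]
    filtered = sorted(
        (s for s in steps if s.cutoff is not None), key=lambda s: s.cutoff
    )
    if len(unfiltered) != 1:
        raise ValueError(
            f"need exactly one unfiltered step, found {len(unfiltered)}"
        )
    if not filtered:
        raise ValueError("need at least one filtered step")
    cutoffs = np.array([s.cutoff for s in filtered], dtype=float)
    if np.any(np.diff(cutoffs) <= 0):
        raise ValueError("filter cutoffs must be strictly increasing")

    total = unfiltered[0].reading
    if total <= 0:
        raise ValueError("unfiltered reading must be positive")

    above = np.array([s.reading / s.transmission for s in filtered])
    high = above > total * (1.0 + excess_tolerance)
    if np.any(high):
        warnings.warn(
            "transmission-corrected reading(s) exceed the unfiltered total at "
            f"cutoffs {cutoffs[high].tolist()} nm; clamping to the total",
            stacklevel=2,
        )
        above = np.minimum(above, total)

    bands = np.empty(cutoffs.size + 1)
    bands[0] = total - above[0]
    bands[1:-1] = above[:-1] - above[1:]
    bands[-1] = above[-1]

    clamped = bool(np.any(bands < 0))
    bands = np.clip(bands, 0.0, None)
    raw_fraction = bands / total
    fraction = raw_fraction / raw_fraction.sum()

    return SpectralBands(
        labels=_band_labels(cutoffs),
        edges=tuple(cutoffs.tolist()),
        irradiance=bands,
        fraction=fraction,
        total=float(total),
        clamped=clamped,
    )
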