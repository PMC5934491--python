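"""Piecewise-constant spectral irradiance densities.

A spectrum here is a non-negative photon flux density (μmol photons
m⁻² s⁻¹ nm⁻¹) that is constant within each wavelength segment and zero
outside the covered range.  Piecewise-constant densities integrate
exactly, which makes them convenient both as ground truth for the
synthetic longpass-filter measurements and as fixtures for checking the
band decomposition against independent quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PiecewiseSpectrum", "DEFAULT_CUTOFFS_NM"]

#: Longpass cutoffs of the filter wheel (nm).
DEFAULT_CUTOFFS_NM: tuple[float, ...] = (400.0, 475.0, 530.0, 590.0, 645.0)


@dataclass(frozen=True)
class PiecewiseSpectrum:
    """Photon flux density, constant on each ``[edges[i], edges[i+1])`` segment.

    Parameters
    ----------
    edges
        Strictly increasing wavelength breakpoints (nm), length ``n + 1``.
    density
        Non-negative density per segment (μmol photons m⁻² s⁻¹ nm⁻¹),
        length ``n``.
    """

    edges: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        density = np.asarray(self.density, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("edges must be a 1-d array of at least two wavelengths")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if density.shape != (edges.size - 1,):
            raise ValueError("density must have one entry per segment")
        if np.any(density < 0) or not np.all(np.isfinite(density)):
            raise ValueError("density must be finite and non-negative")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "density", density)

    # -- integrals ---------------------------------------------------------

    def total(self) -> float:
        """Total irradiance, ∫ density dλ (μmol photons m⁻² s⁻¹)."""
        return float(np.sum(self.density * np.diff(self.edges)))

    def integral_above(self, cutoff: float) -> float:
        """Irradiance above ``cutoff`` nm (what a perfect longpass passes)."""
        lo = np.maximum(self.edges[:-1], cutoff)
        width = np.clip(self.edges[1:] - lo, 0.0, None)
        return float(np.sum(self.density * width))

    def band(self, lo: float, hi: float) -> float:
        """Irradiance between ``lo`` and ``hi`` nm."""
        if hi < lo:
            raise ValueError("band requires lo <= hi")
        return self.integral_above(lo) - self.integral_above(hi)

    def band_irradiances(
        self, cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS_NM
    ) -> np.ndarray:
        """Band integrals for ``<c₁, c₁–c₂, …, >cₙ`` (length ``len(cutoffs)+1``)."""
        cuts = np.asarray(cutoffs, dtype=float)
        if np.any(np.diff(cuts) <= 0):
            raise ValueError("cutoffs must be strictly increasing")
        above = np.array([self.integral_above(c) for c in cuts])
        bands = np.empty(cuts.size + 1)
        bands[0] = self.total() - above[0]
        bands[1:-1] = above[:-1] - above[1:]
        bands[-1] = above[-1]
        return bands

    def band_fractions(
        self, cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS_NM
    ) -> np.ndarray:
        """Band integrals normalized by the total irradiance."""
        total = self.total()
        if total <= 0:
            raise ValueError("spectrum has zero total irradiance")
        return self.band_irradiances(cutoffs) / total

    # -- construction helpers ---------------------------------------------

    def scaled(self, factor: float) -> "PiecewiseSpectrum":
        """Spectrum with every density multiplied by ``factor``."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return PiecewiseSpectrum(self.edges.copy(), self.density * factor)

    def scaled_to_total(self, total: float) -> "PiecewiseSpectrum":
        """Spectrum rescaled so that ``self.total() == total``."""
        current = self.total()
        if current <= 0:
            raise ValueError("cannot rescale a zero spectrum")
        return self.scaled(total / current)

    @classmethod
    def from_band_fractions(
        cls,
        fractions: dict[tuple[float, float], float],
        total: float = 1.0,
    ) -> "PiecewiseSpectrum":
        """Build a spectrum with prescribed irradiance fractions per band.

        ``fractions`` maps ``(lo, hi)`` wavelength intervals (contiguous,
        increasing) to the fraction of the total irradiance they carry.
        """
        items = sorted(fractions.items())
        edges = [items[0][0][0]]
        density = []
        frac_sum = 0.0
        for (lo, hi), frac in items:
            if lo != edges[-1]:
                raise ValueError("band intervals must be contiguous")
            if frac < 0:
                raise ValueError("fractions must be non-negative")
            edges.append(hi)
            density.append(frac / (hi - lo))
            frac_sum += frac
        if not np.isclose(frac_sum, 1.0):
            raise ValueError("band fractions must sum to 1")
        return cls(np.array(edges), np.array(density)).scaled_to_total(total)
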