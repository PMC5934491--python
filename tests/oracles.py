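"""Independent fine-grid quadrature oracle for spectral band integrals.

Integrates a spectral density by the midpoint rule on a 0.1 nm grid,
without using the analytic integrals of ``matbgc.spectra``.  For
piecewise-constant spectra whose breakpoints and cutoffs sit on the
grid, the midpoint rule is exact, so any disagreement with the
longpass decomposition is a defect in the decomposition.
"""

import numpy as np

GRID_STEP = 0.1  # nm


def quadrature_bands(edges, density, cutoffs, lo=300.0, hi=700.0):
    """Band integrals ``<c1, c1-c2, ..., >cn`` by midpoint quadrature."""
    grid = np.arange(lo, hi, GRID_STEP)
    mids = grid + GRID_STEP / 2.0
    # piecewise-constant lookup (no matbgc code involved)
    idx = np.searchsorted(np.asarray(edges), mids, side="right") - 1
    dens = np.zeros_like(mids)
    valid = (idx >= 0) & (idx < len(density))
    dens[valid] = np.asarray(density)[idx[valid]]

    def integral_above(c):
        return float(np.sum(dens[grid >= c]) * GRID_STEP)

    total = float(np.sum(dens) * GRID_STEP)
    above = [integral_above(c) for c in cutoffs]
    bands = [total - above[0]]
    bands += [a - b for a, b in zip(above[:-1], above[1:])]
    bands.append(above[-1])
    return np.array(bands), total


def random_snapped_spectrum(rng, n_segments=6, lo=320.0, hi=680.0):
    """Random piecewise-constant spectrum with breakpoints on the grid."""
    cuts = np.sort(rng.choice(np.arange(lo + 10, hi - 10, GRID_STEP),
                              size=n_segments - 1, replace=False))
    edges = np.round(np.concatenate(([lo], cuts, [hi])), 1)
    density = rng.uniform(0.0, 2.0, n_segments)
    return edges, density
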