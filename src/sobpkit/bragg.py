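"""Pristine Bragg peak depth-dose model.

A single proton energy deposits dose along depth ``z`` following a
range-energy power law (the Bragg-Kleeman rule, ``R = alpha * E^p``).
Differentiating the rule gives the straggling-free stopping kernel

    d0(z; R) = (R - z)^(1/p - 1)   for 0 <= z < R,  else 0,

which diverges (integrably) as the proton stops at its nominal range
``R``: the Bragg peak.  Real beams exhibit range straggling - protons
stop at depths spread around ``R`` - modelled here as a Gaussian
distribution of residual range with standard deviation ``sigma``:

    D(z; R, sigma) = integral of d0(z; r) * phi(r; R, sigma) dr
                     over r in [R - 6 sigma, R + 6 sigma].

The integrand is singular at ``r = z`` (exponent ``1/p - 1`` is about
-0.435 for protons in water), so the quadrature substitutes
``u = (r - z)^(1/p)``; the transformed integrand ``p * phi(z + u^p)`` is
smooth and Gauss-Legendre converges rapidly.

All depths and ranges are mm water-equivalent, with ``z = 0`` at the
phantom surface.  Returned curves are normalized so their maximum is 1;
absolute dose levels are carried by the weights of an SOBP.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.stats import norm

from .errors import InputError, ParameterError

#: Bragg-Kleeman exponent for protons in water.
DEFAULT_EXPONENT_P = 1.77

#: Default depth-grid spacing, mm.
DEFAULT_GRID_STEP = 0.1

#: Number of Gauss-Legendre nodes for the straggling quadrature.
DEFAULT_QUAD_NODES = 96

#: Relative tolerance for the uniform-grid-spacing invariant.
_GRID_RTOL = 1e-9


def default_straggling_sigma(nominal_range: float) -> float:
    """Range-straggling width from the standard scaling sigma = 0.012 R^0.935.

    Parameters
    ----------
    nominal_range
        Peak nominal range in mm water-equivalent.

    Returns
    -------
    float
        Gaussian straggling sigma in mm (about 1.3 mm at R = 150 mm).
    """
    return 0.012 * float(nominal_range) ** 0.935


@dataclasses.dataclass(frozen=True)
class PristinePeak:
    """Parameters of one pristine (single-energy) Bragg peak.

    Attributes
    ----------
    nominal_range
        Depth in mm water-equivalent at which the straggling-free proton
        stops; must be positive.
    straggling_sigma
        Standard deviation (mm) of the Gaussian range spread.  ``None``
        (the default) means "use the default scaling rule", and the rule
        is re-applied whenever the nominal range changes (e.g. under a
        range-modulation shift).  An explicit value, including 0, is
        kept as set.
    exponent_p
        Bragg-Kleeman power-law exponent; must exceed 1.
    """

    nominal_range: float
    straggling_sigma: float | None = None
    exponent_p: float = DEFAULT_EXPONENT_P

    def __post_init__(self) -> None:
        if not self.nominal_range > 0:
            raise ParameterError(
                f"nominal_range must be > 0, got {self.nominal_range}"
            )
        if self.straggling_sigma is not None and self.straggling_sigma < 0:
            raise ParameterError(
                f"straggling_sigma must be >= 0, got {self.straggling_sigma}"
            )
        if not self.exponent_p > 1:
            raise ParameterError(
                f"exponent_p must be > 1, got {self.exponent_p}"
            )

    @property
    def sigma(self) -> float:
        """Effective straggling sigma in mm (explicit value or default rule)."""
        if self.straggling_sigma is None:
            return default_straggling_sigma(self.nominal_range)
        return float(self.straggling_sigma)

    def shifted(self, range_shift: float) -> "PristinePeak":
        """Return a copy with the nominal range shifted by ``range_shift`` mm.

        A peak using the default sigma rule keeps using it, so its
        straggling is recomputed from the shifted range.
        """
        new_range = self.nominal_range + range_shift
        if new_range <= 0:
            raise InputError(
                f"range shift {range_shift} mm drives nominal range "
                f"{self.nominal_range} mm non-positive"
            )
        return dataclasses.replace(self, nominal_range=new_range)


@dataclasses.dataclass(frozen=True)
class DepthDoseCurve:
    """A relative depth-dose curve on a uniform depth grid.

    ``depths`` are mm water-equivalent, strictly increasing with uniform
    spacing; ``values`` are relative dose in arbitrary units, all
    nonnegative.  This is the universal exchange object of the package.
    """

    depths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "values", values)
        if depths.ndim != 1 or values.ndim != 1:
            raise InputError("depths and values must be 1-D")
        if depths.size != values.size:
            raise InputError(
                f"length mismatch: {depths.size} depths, {values.size} values"
            )
        if depths.size < 2:
            raise InputError("a curve needs at least two grid points")
        steps = np.diff(depths)
        if not np.all(steps > 0):
            raise InputError("depths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=_GRID_RTOL, atol=0.0):
            raise InputError("depth grid must be uniformly spaced")
        if np.any(values < 0):
            raise InputError("dose values must be nonnegative")

    @property
    def spacing(self) -> float:
        """Grid spacing in mm."""
        return float(self.depths[1] - self.depths[0])

    @property
    def max_value(self) -> float:
        return float(self.values.max())

    @property
    def argmax_depth(self) -> float:
        """Depth (mm) of the maximum dose value."""
        return float(self.depths[int(np.argmax(self.values))])

    def with_values(self, values: np.ndarray) -> "DepthDoseCurve":
        """Same grid, new values."""
        return DepthDoseCurve(self.depths, values)

    def scaled(self, factor: float) -> "DepthDoseCurve":
        return self.with_values(self.values * factor)

    def normalized(self) -> "DepthDoseCurve":
        """Scale so the maximum value is 1."""
        m = self.max_value
        if m <= 0:
            raise InputError("cannot normalize an all-zero curve")
        return self.scaled(1.0 / m)

    def interpolate(self, depth) -> np.ndarray:
        """Linear interpolation of dose at arbitrary depth(s), 0 outside."""
        return np.interp(depth, self.depths, self.values, left=0.0, right=0.0)


def make_grid(min_mm: float, max_mm: float, step_mm: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Uniform depth grid [min_mm, max_mm] inclusive with spacing step_mm."""
    if step_mm <= 0:
        raise InputError(f"grid step must be > 0, got {step_mm}")
    if max_mm <= min_mm:
        raise InputError("grid max must exceed grid min")
    n = int(round((max_mm - min_mm) / step_mm))
    return min_mm + step_mm * np.arange(n + 1)


def stopping_kernel(z: np.ndarray, nominal_range: float, exponent_p: float) -> np.ndarray:
    """Straggling-free kernel (R - z)^(1/p - 1) on [0, R), 0 elsewhere."""
    z = np.asarray(z, dtype=float)
    out = np.zeros_like(z)
    mask = (z >= 0) & (z < nominal_range)
    out[mask] = (nominal_range - z[mask]) ** (1.0 / exponent_p - 1.0)
    return out


def _validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InputError("empty depth grid")
    if grid.size < 2:
        raise InputError("depth grid needs at least two points")
    step = grid[1] - grid[0]
    if step > 0.5 + 1e-12:
        raise InputError(
            f"grid spacing {step:.3g} mm exceeds the 0.5 mm maximum"
        )
    if np.any(grid < 0):
        raise InputError("depths must be nonnegative")
    return grid


def pristine_depth_dose(
    peak: PristinePeak,
    grid: np.ndarray,
    quad_nodes: int = DEFAULT_QUAD_NODES,
    normalize: bool = True,
) -> DepthDoseCurve:
    """Depth-dose curve of one pristine Bragg peak on the given grid.

    Convolves the power-law stopping kernel with the Gaussian range
    distribution by Gauss-Legendre quadrature (after the singularity-
    removing substitution described in the module docstring).  With
    ``straggling_sigma == 0`` the closed-form kernel is returned.

    Parameters
    ----------
    peak
        Peak parameters.
    grid
        Depth grid, mm; spacing must not exceed 0.5 mm.
    quad_nodes
        Gauss-Legendre node count; the default converges well below
        1e-4 relative error for clinical sigma.
    normalize
        If True (default) the curve is scaled so its maximum is 1.

    Returns
    -------
    DepthDoseCurve
        Relative dose; exactly 0 beyond ``R + 6 sigma``.
    """
    grid = _validate_grid(grid)
    R = peak.nominal_range
    p = peak.exponent_p
    sigma = peak.sigma

    if sigma == 0.0:
        values = stopping_kernel(grid, R, p)
    else:
        lo = R - 6.0 * sigma
        hi = R + 6.0 * sigma
        # u = (r - z)^(1/p): integral becomes p * phi(z + u^p) du, smooth.
        u_lo = np.clip(np.maximum(lo, grid) - grid, 0.0, None) ** (1.0 / p)
        u_hi = np.clip(hi - grid, 0.0, None) ** (1.0 / p)
        nodes, weights = leggauss(quad_nodes)
        half = 0.5 * (u_hi - u_lo)
        mid = 0.5 * (u_hi + u_lo)
        u = mid[:, None] + half[:, None] * nodes[None, :]
        r = grid[:, None] + u ** p
        integrand = norm.pdf(r, loc=R, scale=sigma)
        values = p * half * (integrand * weights[None, :]).sum(axis=1)
        values = np.clip(values, 0.0, None)

    curve = DepthDoseCurve(grid, values)
    return curve.normalized() if normalize else curve


@functools.lru_cache(maxsize=512)
def peak_max_depth(peak: PristinePeak, step: float = 0.02) -> float:
    """Depth (mm) of the straggled pristine curve's maximum.

    Evaluated on an internal fine grid (default 0.02 mm spacing) spanning
    the peak region, so the result does not depend on the caller's grid.
    For ``sigma == 0`` the kernel diverges at ``R`` and the returned depth
    is the last grid point below ``R``.
    """
    sigma = peak.sigma
    R = peak.nominal_range
    lo = max(0.0, R - max(6.0 * sigma, 2.0) - 2.0)
    hi = R + 6.0 * sigma + step
    fine = make_grid(lo, hi, step)
    curve = pristine_depth_dose(peak, fine)
    return curve.argmax_depth
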