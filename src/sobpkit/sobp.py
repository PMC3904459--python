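"""Spread-out Bragg peak (SOBP) composition and plateau-weight solving.

An SOBP is a weighted sum of pristine Bragg peaks at staggered ranges.
Weights are chosen by nonnegative least squares so the composed physical
dose is flat at the prescription level across the plateau - the interval
from the shallowest peak's nominal range to the distal range, shrunk
inward by a small margin at each end to keep edge ripple out of the fit.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import nnls

from .bragg import (
    DEFAULT_GRID_STEP,
    DepthDoseCurve,
    PristinePeak,
    make_grid,
    pristine_depth_dose,
)
from .errors import ConfigurationError, InputError, ParameterError

#: Default spacing between adjacent pristine peaks, mm water-equivalent.
DEFAULT_PEAK_SPACING = 6.0

#: Default plateau margin at each end, mm.
DEFAULT_PLATEAU_MARGIN = 1.0

#: Default prescription level, arbitrary units (100 => doses read as %).
DEFAULT_PRESCRIPTION = 100.0


@dataclasses.dataclass(frozen=True)
class SOBPSpec:
    """Specification of an SOBP delivery.

    Attributes
    ----------
    distal_range
        Nominal range (mm) of the deepest pristine peak.
    num_peaks
        Number of pristine peaks, staggered proximally.
    peak_spacing
        Range spacing between adjacent peaks, mm (delivery-system
        property; default 6 mm).
    plateau_margin
        The plateau used for weight fitting is
        [shallowest range + margin, distal_range - margin].
    prescription_level
        Target plateau dose in arbitrary units; the default 100 makes
        reported doses read as percentages of prescription.
    """

    distal_range: float
    num_peaks: int = 4
    peak_spacing: float = DEFAULT_PEAK_SPACING
    plateau_margin: float = DEFAULT_PLATEAU_MARGIN
    prescription_level: float = DEFAULT_PRESCRIPTION

    def __post_init__(self) -> None:
        if self.num_peaks < 1:
            raise ParameterError(f"num_peaks must be >= 1, got {self.num_peaks}")
        if self.peak_spacing <= 0:
            raise ParameterError(
                f"peak_spacing must be > 0, got {self.peak_spacing}"
            )
        if self.distal_range <= 0:
            raise ParameterError(
                f"distal_range must be > 0, got {self.distal_range}"
            )
        if self.prescription_level <= 0:
            raise ParameterError("prescription_level must be > 0")
        lo, hi = self.plateau
        if not lo < hi:
            raise ConfigurationError(
                f"plateau [{lo}, {hi}] mm is empty after the "
                f"{self.plateau_margin} mm margins"
            )

    @property
    def shallowest_range(self) -> float:
        return self.distal_range - (self.num_peaks - 1) * self.peak_spacing

    @property
    def plateau(self) -> tuple[float, float]:
        """(lo, hi) plateau interval in mm used for weight fitting."""
        if self.num_peaks == 1:
            # Degenerate plateau around the single peak's maximum region.
            return (
                self.distal_range - self.plateau_margin,
                self.distal_range + self.plateau_margin,
            )
        return (
            self.shallowest_range + self.plateau_margin,
            self.distal_range - self.plateau_margin,
        )


@dataclasses.dataclass(frozen=True)
class WeightedBeam:
    """A set of pristine peaks with nonnegative weights: one SOBP delivery.

    ``plateau`` records the interval the weights were fitted on; it is
    carried along so downstream metrics use the same reference region.
    """

    components: tuple[tuple[PristinePeak, float], ...]
    prescription_level: float = DEFAULT_PRESCRIPTION
    plateau: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        components = tuple((pk, float(w)) for pk, w in self.components)
        object.__setattr__(self, "components", components)
        if not components:
            raise ParameterError("a beam needs at least one component")
        if any(w < 0 for _, w in components):
            raise ParameterError("weights must be nonnegative")
        if not any(w > 0 for _, w in components):
            raise ParameterError("at least one weight must be positive")

    @property
    def peaks(self) -> tuple[PristinePeak, ...]:
        return tuple(pk for pk, _ in self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.components])

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def max_sigma(self) -> float:
        return max(pk.sigma for pk, _ in self.components)

    @property
    def distal_range(self) -> float:
        return max(pk.nominal_range for pk, _ in self.components)

    def default_grid(self, step: float = DEFAULT_GRID_STEP) -> np.ndarray:
        """Grid [0, distal range + 10 mm] at the given spacing."""
        return make_grid(0.0, self.distal_range + 10.0, step)


def _peak_key(peak: PristinePeak) -> tuple[float, float, float]:
    return (
        round(peak.nominal_range, 12),
        round(peak.sigma, 12),
        round(peak.exponent_p, 12),
    )


def solve_weights(
    components: list[PristinePeak],
    plateau: tuple[float, float],
    target: float,
    grid: np.ndarray,
) -> np.ndarray:
    """Nonnegative least-squares weights flattening the plateau at ``target``.

    Minimizes the sum of squared deviations of the composed dose from
    ``target`` over the grid points inside ``plateau``, subject to all
    weights being nonnegative.  Duplicate peaks make the design singular;
    a warning is issued and the total weight of each duplicate group is
    split equally (the minimum-Euclidean-norm minimizer).

    Parameters
    ----------
    components
        Pristine peaks (at least one).
    plateau
        (lo, hi) interval in mm; must contain at least 10 grid points.
    target
        Plateau dose level in arbitrary units.
    grid
        Shared depth grid for all components.

    Returns
    -------
    numpy.ndarray
        One nonnegative weight per component.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = plateau
    mask = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
    if mask.sum() < 10:
        raise InputError(
            f"plateau [{lo}, {hi}] mm holds only {int(mask.sum())} grid "
            "points; at least 10 required"
        )
    curves = [pristine_depth_dose(pk, grid) for pk in components]
    columns = [c.values[mask] for c in curves]

    # Group exactly duplicate peaks: NNLS sees one column per group, and
    # the group's weight is split equally (minimum-norm tie-break).
    groups: dict[tuple, list[int]] = {}
    for i, pk in enumerate(components):
        groups.setdefault(_peak_key(pk), []).append(i)
    if any(len(idx) > 1 for idx in groups.values()):
        warnings.warn(
            "duplicate pristine peaks make the weight design singular; "
            "splitting weight equally within each duplicate group",
            stacklevel=2,
        )
    rep_indices = [idx[0] for idx in groups.values()]
    A = np.column_stack([columns[i] for i in rep_indices])
    b = np.full(int(mask.sum()), float(target))
    w_rep, _ = nnls(A, b)

    weights = np.zeros(len(components))
    for w_g, idx in zip(w_rep, groups.values()):
        for i in idx:
            weights[i] = w_g / len(idx)
    return weights


def build_sobp(spec: SOBPSpec, grid: np.ndarray | None = None) -> WeightedBeam:
    """Build the SOBP delivery for ``spec``: peaks, plateau, solved weights.

    Peaks sit at nominal ranges ``distal_range - k * peak_spacing`` for
    ``k = 0 .. num_peaks - 1`` with straggling from the default sigma
    rule.  Weights come from :func:`solve_weights` on the plateau.
    """
    ranges = [
        spec.distal_range - k * spec.peak_spacing for k in range(spec.num_peaks)
    ]
    if min(ranges) <= 0:
        raise ConfigurationError(
            f"shallowest peak range {min(ranges):.1f} mm is non-positive; "
            "reduce num_peaks or peak_spacing"
        )
    if grid is None:
        grid = make_grid(0.0, spec.distal_range + 10.0, DEFAULT_GRID_STEP)
    peaks = [PristinePeak(nominal_range=r) for r in ranges]
    if spec.num_peaks == 1:
        # Degenerate plateau: deliver the prescription at the peak maximum.
        peak_max = pristine_depth_dose(peaks[0], grid).max_value
        weights = np.array([spec.prescription_level / peak_max])
    else:
        weights = solve_weights(
            peaks, spec.plateau, spec.prescription_level, grid
        )
    return WeightedBeam(
        components=tuple(zip(peaks, weights)),
        prescription_level=spec.prescription_level,
        plateau=spec.plateau,
    )


def compose(beam: WeightedBeam, grid: np.ndarray) -> DepthDoseCurve:
    """Physical depth-dose of the beam: sum of weight x pristine curve."""
    grid = np.asarray(grid, dtype=float)
    total = np.zeros_like(grid)
    for peak, weight in beam.components:
        if weight == 0.0:
            continue
        total += weight * pristine_depth_dose(peak, grid).values
    return DepthDoseCurve(grid, total)
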