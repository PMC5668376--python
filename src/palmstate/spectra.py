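"""From spectra to palmitoylation-state distributions.

Intact-protein electrospray spectra show each palmitoylation state as a
ladder of peaks spaced by the palmitoyl delta mass (~238.4 Da), replicated
across the charge-state envelope. The pipeline here is: pick peaks in the
m/z (or neutral-mass) domain, optionally collapse the charge series to
neutral masses, assign the peaks to the base-mass + n·delta ladder, and
convert integrated peak areas into state fractions.

Peak areas are trapezoidal integrals between flanking local minima — no
peak-shape model is assumed, matching how relative levels are read off
deconvoluted spectra in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .masscalc import PROTON_MASS, palmitoyl_delta
from .model import StateDistribution

__all__ = [
    "MzSpectrum",
    "Peak",
    "DeconvolutionResult",
    "LadderAssignment",
    "pick_peaks",
    "deconvolute_charge_series",
    "assign_palmitoyl_ladder",
    "classify_site",
]

#: Default ladder spacing: average mass of one thioester-linked palmitoyl.
DEFAULT_DELTA = palmitoyl_delta("average").value


@dataclass(frozen=True)
class MzSpectrum:
    """A continuum spectrum: paired m/z (or mass) and intensity arrays."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if mz.size and (np.diff(mz) <= 0).any():
            raise ValueError("m/z values must be strictly increasing")
        if mz.size and mz[0] <= 0:
            raise ValueError("m/z values must be positive")
        if (intensity < 0).any():
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)


@dataclass(frozen=True)
class Peak:
    """A picked peak: apex position/intensity, integrated area, bounds."""

    position: float
    apex_intensity: float
    area: float
    left: float
    right: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("peak area must be non-negative")
        if not self.left <= self.position <= self.right:
            raise ValueError("peak bounds must bracket the apex")


@dataclass(frozen=True)
class DeconvolutionResult:
    """Neutral-mass species plus any peaks with no consistent charge."""

    species: Tuple[Peak, ...]
    unassigned: Tuple[Peak, ...]
    charges: Tuple[int, ...]


@dataclass(frozen=True)
class LadderAssignment:
    """Mapping of neutral-mass peaks to the base + n·delta palmitoyl ladder."""

    base_mass: float
    delta: float
    tolerance: float
    state_areas: Tuple[float, ...]
    assigned: Tuple[Tuple[int, Peak], ...]
    unassigned: Tuple[Peak, ...]
    distribution: StateDistribution


def _flank_minimum(y: np.ndarray, apex: int, step: int, rise_frac: float = 0.05) -> int:
    """Index of the effective flanking minimum next to a peak apex.

    Walks outward tracking the running minimum and stops once the signal
    has fallen below half the apex and risen back by ``rise_frac`` of the
    drop — small baseline-noise upticks do not terminate the walk, so
    integration bounds reach the true inter-peak valley.
    """
    run_min = y[apex]
    min_idx = apex
    i = apex
    while 0 < i < y.size - 1:
        i += step
        if y[i] < run_min:
            run_min = y[i]
            min_idx = i
        elif (
            run_min < 0.5 * y[apex]
            and y[i] > run_min + rise_frac * (y[apex] - run_min)
        ):
            break
    return min_idx


def pick_peaks(
    spectrum: MzSpectrum,
    min_relative_intensity: float = 0.02,
    min_prominence: float = 0.02,
) -> List[Peak]:
    """Local maxima above intensity/prominence thresholds, with trapezoidal
    areas integrated between the flanking local minima.

    Thresholds are fractions of the base peak (most intense point), so the
    peak list is invariant to uniform intensity scaling.
    """
    if spectrum.mz.size == 0:
        raise ValueError("cannot pick peaks in an empty spectrum")
    top = float(spectrum.intensity.max(initial=0.0))
    if top <= 0:
        return []
    indices, _ = find_peaks(
        spectrum.intensity,
        height=min_relative_intensity * top,
        prominence=min_prominence * top,
    )
    peaks: List[Peak] = []
    y = spectrum.intensity
    x = spectrum.mz
    for apex in indices:
        left = _flank_minimum(y, apex, -1)
        right = _flank_minimum(y, apex, +1)
        area = float(np.trapezoid(y[left : right + 1], x[left : right + 1]))
        peaks.append(
            Peak(
                position=float(x[apex]),
                apex_intensity=float(y[apex]),
                area=area,
                left=float(x[left]),
                right=float(x[right]),
            )
        )
    return peaks


def _neutral_mass(mz: float, z: int) -> float:
    return z * mz - z * PROTON_MASS


def deconvolute_charge_series(
    peaks: Sequence[Peak],
    charge_range: Tuple[int, int],
    tolerance: float = 2.0,
) -> DeconvolutionResult:
    """Collapse an electrospray charge-state envelope to neutral masses.

    Each m/z peak at charge z corresponds to neutral mass
    M = z·(m/z) − z·1.00728. When the charge range holds more than one
    candidate, each peak takes the charge whose implied neutral mass is
    corroborated by the most other peaks (within ``tolerance``); ties go
    to the lower charge. Corroborated peaks are merged per species
    (area-weighted mean mass, areas summed); peaks supported by no other
    peak are reported as unassigned rather than silently dropped.
    """
    z_lo, z_hi = charge_range
    if z_lo < 1 or z_hi < z_lo:
        raise ValueError(f"invalid charge range {charge_range}")
    charges = list(range(z_lo, z_hi + 1))
    peaks = list(peaks)
    if not peaks:
        return DeconvolutionResult((), (), tuple(charges))

    if len(charges) == 1:
        z = charges[0]
        species = [
            Peak(_neutral_mass(p.position, z), p.apex_intensity, p.area,
                 _neutral_mass(p.left, z), _neutral_mass(p.right, z))
            for p in peaks
        ]
        return DeconvolutionResult(tuple(sorted(species, key=lambda p: p.position)),
                                   (), tuple(charges))

    if len(peaks) < 2:
        raise ValueError("charge inference requires at least two peaks")

    masses = np.array(
        [[_neutral_mass(p.position, z) for z in charges] for p in peaks]
    )
    best_charge: List[Optional[int]] = []
    for i in range(len(peaks)):
        support_best, z_best = -1, None
        for j, z in enumerate(charges):
            mi = masses[i, j]
            # count peaks (other than i) corroborating this mass at any charge
            support = sum(
                1
                for k in range(len(peaks))
                if k != i and np.min(np.abs(masses[k] - mi)) <= tolerance
            )
            if support > support_best:  # ties keep the earlier, lower charge
                support_best, z_best = support, z
        best_charge.append(z_best if support_best > 0 else None)

    assigned = [
        (p, _neutral_mass(p.position, z), z)
        for p, z in zip(peaks, best_charge)
        if z is not None
    ]
    unassigned = tuple(p for p, z in zip(peaks, best_charge) if z is None)

    # merge assigned peaks whose neutral masses agree within tolerance
    assigned.sort(key=lambda t: t[1])
    species: List[Peak] = []
    group: List[Tuple[Peak, float, int]] = []

    def _flush() -> None:
        if not group:
            return
        areas = np.array([p.area for p, _, _ in group])
        ms = np.array([m for _, m, _ in group])
        w = areas if areas.sum() > 0 else np.ones_like(areas)
        mass = float(np.average(ms, weights=w))
        species.append(
            Peak(
                position=mass,
                apex_intensity=float(max(p.apex_intensity for p, _, _ in group)),
                area=float(areas.sum()),
                left=mass - tolerance,
                right=mass + tolerance,
            )
        )

    for item in assigned:
        if group and item[1] - group[-1][1] > tolerance:
            _flush()
            group = []
        group.append(item)
    _flush()
    return DeconvolutionResult(tuple(species), unassigned, tuple(charges))


def assign_palmitoyl_ladder(
    masses: Sequence[Peak],
    base_mass: float,
    delta: float = DEFAULT_DELTA,
    tolerance: float = 1.5,
    n_max: int = 5,
) -> LadderAssignment:
    """Assign neutral-mass peaks to the palmitoyl ladder and quantify states.

    A peak of mass M lands on rung n = round((M − base)/delta) when its
    residual from base + n·delta is within ``tolerance`` and 0 ≤ n ≤ n_max.
    State fractions are per-rung integrated areas over the total assigned
    area; rungs with no peak get fraction 0. Two peaks on one rung are
    summed.
    """
    if base_mass <= 0:
        raise ValueError("base_mass must be positive")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    state_areas = np.zeros(n_max + 1)
    assigned: List[Tuple[int, Peak]] = []
    unassigned: List[Peak] = []
    for peak in masses:
        n = int(round((peak.position - base_mass) / delta))
        expected = base_mass + n * delta
        if 0 <= n <= n_max and abs(peak.position - expected) <= tolerance:
            state_areas[n] += peak.area
            assigned.append((n, peak))
        else:
            unassigned.append(peak)
    total = state_areas.sum()
    if total <= 0:
        raise ValueError("no peaks assigned to the palmitoyl ladder")
    distribution = StateDistribution(tuple(state_areas / total))
    return LadderAssignment(
        base_mass=base_mass,
        delta=delta,
        tolerance=tolerance,
        state_areas=tuple(state_areas),
        assigned=tuple(assigned),
        unassigned=tuple(unassigned),
        distribution=distribution,
    )


def classify_site(avg_state: float, threshold: float = 0.2) -> bool:
    """Call an engineered cysteine a palmitoylation site when the average
    palmitoylation state reaches the threshold (inclusive)."""
    if avg_state < 0:
        raise ValueError("average palmitoylation state must be non-negative")
    return avg_state >= threshold
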