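"""Synthetic study data: construct panels and charge-state spectra.

Two named scenarios reproduce the published study designs:

* :func:`cld3_scenario` — claudin-3 with four native palmitoylation sites
  (Cys 103, 106, 182, 184) plus a low-occupancy (~10%) extra site
  introduced by the cloning strategy, across all ten constructs (wild
  type, the four triple-site mutants, the four single-site mutants, and
  the Cys-free ΔCys variant). Generating parameters p = (0.69, 0.69,
  0.86, 0.64, 0.10) with cooperativity c = 1.24.
* :func:`cd20_scenario` — CD20 with two sites (Cys 111, Cys 220),
  p = (0.74, 0.82), c = 1.51; wild type plus the two single-site mutants.

Panels are sampled with multinomial counting noise (default 1000 molecules
per replicate, biological triplicates), and spectra as Gaussian charge-state
envelopes of the palmitoyl ladder. Everything is bit-reproducible given a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Tuple

import numpy as np

from .masscalc import PROTON_MASS
from .model import (
    ConstructSpec,
    ModelParams,
    SitePanel,
    StateDistribution,
    cooperative_distribution,
)
from .fitting import Observation
from .spectra import DEFAULT_DELTA, MzSpectrum

__all__ = [
    "Scenario",
    "SpectrumModel",
    "cld3_scenario",
    "cd20_scenario",
    "generate_panel",
    "simulate_spectrum",
]


@dataclass(frozen=True)
class Scenario:
    """A generating model plus the construct panel that observes it."""

    name: str
    params: ModelParams
    constructs: Tuple[ConstructSpec, ...]
    counts: int = 1000
    replicates: int = 3
    seed: int = 0
    base_mass: float = 23000.0  # claudin-scale; irrelevant to model fitting

    def __post_init__(self) -> None:
        if self.counts < 1:
            raise ValueError("counts must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        panel_sites = set(self.params.panel.sites)
        for spec in self.constructs:
            unknown = set(spec.sites) - panel_sites
            if unknown:
                raise ValueError(
                    f"construct {spec.construct_id!r} references unknown "
                    f"sites {sorted(unknown)}"
                )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "params": self.params.to_dict(),
            "constructs": [
                {"construct_id": s.construct_id, "sites": list(s.sites)}
                for s in self.constructs
            ],
            "counts": self.counts,
            "replicates": self.replicates,
            "seed": self.seed,
            "base_mass": self.base_mass,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        return cls(
            name=data["name"],
            params=ModelParams.from_dict(data["params"]),
            constructs=tuple(
                ConstructSpec(d["construct_id"], tuple(d["sites"]))
                for d in data["constructs"]
            ),
            counts=int(data.get("counts", 1000)),
            replicates=int(data.get("replicates", 3)),
            seed=int(data.get("seed", 0)),
            base_mass=float(data.get("base_mass", 23000.0)),
        )


@dataclass(frozen=True)
class SpectrumModel:
    """Gaussian peak model for simulating charge-state envelopes."""

    base_mass: float = 23000.0
    delta: float = DEFAULT_DELTA
    charges: Tuple[int, ...] = (10, 11, 12, 13)
    sigma: float = 3.0  # peak width in the neutral-mass domain, Da
    noise: float = 0.005  # baseline noise relative to the tallest peak
    intensity_scale: float = 1000.0
    grid_step: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if any(z < 1 for z in self.charges) or not self.charges:
            raise ValueError("charges must be positive integers")


def cld3_scenario(seed: int = 0) -> Scenario:
    """Claudin-3 panel: 4 native sites + ~10% cloning-artifact site.

    Ten constructs: wild type (all five sites), the four combinations of
    three native sites, the four single-native-site mutants, and the ΔCys
    variant carrying only the artifact site.
    """
    native = ("C103", "C106", "C182", "C184")
    panel = SitePanel(native + ("extra",))
    params = ModelParams(panel=panel, p=(0.69, 0.69, 0.86, 0.64, 0.10), c=1.24)
    constructs: List[ConstructSpec] = [ConstructSpec("WT", panel.sites)]
    for triple in combinations(native, 3):
        missing = next(s for s in native if s not in triple)
        constructs.append(
            ConstructSpec(f"triple_no_{missing}", triple + ("extra",))
        )
    for single in native:
        constructs.append(ConstructSpec(f"single_{single}", (single, "extra")))
    constructs.append(ConstructSpec("dCys", ("extra",)))
    return Scenario(
        name="cld3", params=params, constructs=tuple(constructs), seed=seed
    )


def cd20_scenario(seed: int = 0) -> Scenario:
    """CD20 panel: wild type plus the two single-site mutants."""
    panel = SitePanel(("C111", "C220"))
    params = ModelParams(panel=panel, p=(0.74, 0.82), c=1.51)
    constructs = (
        ConstructSpec("WT", ("C111", "C220")),
        ConstructSpec("single_C111", ("C111",)),
        ConstructSpec("single_C220", ("C220",)),
    )
    return Scenario(name="cd20", params=params, constructs=constructs, seed=seed)


def generate_panel(
    scenario: Scenario,
    noiseless: bool = False,
    counts: Optional[int] = None,
    replicates: Optional[int] = None,
    seed: Optional[int] = None,
) -> List[Observation]:
    """Observed state fractions per construct and replicate.

    Noiseless panels return the exact cooperative-model distribution;
    noisy panels draw multinomial state counts (``counts`` molecules per
    replicate) with a deterministic per-(construct, replicate) stream so
    any subset of the panel is reproducible in isolation.
    """
    counts = scenario.counts if counts is None else counts
    replicates = scenario.replicates if replicates is None else replicates
    seed = scenario.seed if seed is None else seed
    observations: List[Observation] = []
    for ci, spec in enumerate(scenario.constructs):
        dist = cooperative_distribution(scenario.params, spec)
        truth = dist.as_array()
        for ri in range(replicates):
            if noiseless:
                fractions = truth
            else:
                rng = np.random.default_rng([seed, ci, ri])
                fractions = rng.multinomial(counts, truth) / counts
            observations.append(
                Observation(spec.construct_id, f"rep{ri + 1}", tuple(fractions))
            )
    return observations


def simulate_spectrum(
    dist: StateDistribution,
    spec: SpectrumModel = SpectrumModel(),
    seed: int = 0,
) -> MzSpectrum:
    """Continuum m/z spectrum of a palmitoyl ladder over a charge envelope.

    Each (charge z, state n) pair contributes a Gaussian at
    (base + n·delta + z·1.00728)/z with area proportional to the state
    fraction and width sigma/z, plus seeded additive baseline noise.
    """
    fractions = dist.as_array()
    centers, sigmas, areas = [], [], []
    for z in spec.charges:
        for n, fraction in enumerate(fractions):
            mass = spec.base_mass + n * spec.delta
            centers.append((mass + z * PROTON_MASS) / z)
            sigmas.append(spec.sigma / z)
            areas.append(spec.intensity_scale * fraction)
    centers = np.array(centers)
    sigmas = np.array(sigmas)
    areas = np.array(areas)

    pad = 8.0 * sigmas.max() + spec.delta / max(spec.charges)
    lo, hi = centers.min() - pad, centers.max() + pad
    step = spec.grid_step or sigmas.min() / 6.0
    mz = np.arange(lo, hi, step)
    intensity = np.zeros_like(mz)
    for mu, s, a in zip(centers, sigmas, areas):
        if a <= 0:
            continue
        intensity += a / (s * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((mz - mu) / s) ** 2
        )
    if spec.noise > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(
            0.0, spec.noise * intensity.max(), size=intensity.size
        )
        intensity = np.clip(intensity, 0.0, None)
    return MzSpectrum(mz=mz, intensity=intensity)
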