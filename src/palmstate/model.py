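"""Stochastic and cooperative multi-site palmitoylation-state models.

A membrane protein with k cysteine sites, each palmitoylated independently
with probability p_i, carries n attached palmitates with Poisson-binomial
probability P(n). Cooperativity is introduced through the conditional gain
P(n+1|n) = P(n+1)/P(n): the cooperative model scales it by c**n, which is
equivalent to reweighting states as

    P_coop(n) ∝ c**(n*(n-1)/2) * P(n),

renormalized over n = 0..n_max. c = 1 recovers the independent model; c > 1
shifts mass toward higher palmitoylation states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import numpy as np

__all__ = [
    "SitePanel",
    "ModelParams",
    "ConstructSpec",
    "StateDistribution",
    "independent_distribution",
    "cooperative_distribution",
    "conditional_gain",
    "distribution_summary",
    "cooperativity_exponent",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SitePanel:
    """Ordered, unique palmitoylation-site labels; fixes the p_i indexing."""

    sites: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("site identifiers must be unique")

    def __len__(self) -> int:
        return len(self.sites)

    def index(self, site: str) -> int:
        try:
            return self.sites.index(site)
        except ValueError:
            raise KeyError(f"unknown site {site!r}") from None


@dataclass(frozen=True)
class ModelParams:
    """Per-site palmitoylation probabilities plus a cooperativity parameter.

    ``p[i]`` is the probability that site ``panel.sites[i]`` carries a
    palmitate; ``c`` is the multiplicative cooperativity (c = 1 ⇔ sites are
    independent).
    """

    panel: SitePanel
    p: Tuple[float, ...]
    c: float = 1.0

    def __post_init__(self) -> None:
        if len(self.p) != len(self.panel):
            raise ValueError("length of p must equal panel size")
        for site, pi in zip(self.panel.sites, self.p):
            if not 0.0 <= pi <= 1.0:
                raise ValueError(f"p[{site}] = {pi} outside [0, 1]")
        if not self.c > 0:
            raise ValueError(f"cooperativity c must be > 0, got {self.c}")

    def probability(self, site: str) -> float:
        return self.p[self.panel.index(site)]

    def to_dict(self) -> dict:
        return {"sites": list(self.panel.sites), "p": list(self.p), "c": self.c}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        return cls(
            panel=SitePanel(tuple(data["sites"])),
            p=tuple(float(x) for x in data["p"]),
            c=float(data.get("c", 1.0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ConstructSpec:
    """A protein construct defined by the subset of panel sites it carries.

    Wild type carries every site; site-directed Cys→Ala mutants carry fewer.
    An empty construct (no sites) is legal and is certain to be unmodified.
    """

    construct_id: str
    sites: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("construct sites must be unique")

    @property
    def n_max(self) -> int:
        return len(self.sites)

    def site_probabilities(self, params: ModelParams) -> np.ndarray:
        return np.array([params.probability(s) for s in self.sites])


@dataclass(frozen=True)
class StateDistribution:
    """Normalized fractions over palmitoylation states n = 0..n_max."""

    fractions: Tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.fractions, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("fractions must be a non-empty 1-D sequence")
        if (arr < -_SUM_TOL).any():
            raise ValueError("fractions must be non-negative")
        if abs(arr.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"fractions sum to {arr.sum()!r}, expected 1")

    @property
    def n_max(self) -> int:
        return len(self.fractions) - 1

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    def mean_state(self) -> float:
        arr = self.as_array()
        return float(np.arange(arr.size) @ arr)

    def mode_state(self) -> int:
        # smallest n among maxima; ties resolved toward fewer palmitates
        return int(np.argmax(self.fractions))


def _poisson_binomial(p: np.ndarray) -> np.ndarray:
    """P(n) for independent sites via generating-function convolution.

    Sequentially multiplies the polynomials (1 - p_i) + p_i * x; the
    coefficient of x**n after k factors is the probability of n successes.
    O(k^2), exact for probabilities at 0 or 1.
    """
    poly = np.array([1.0])
    for pi in p:
        poly = np.convolve(poly, np.array([1.0 - pi, pi]))
    return poly


def cooperativity_exponent(n: int) -> int:
    """Exponent of c applied to state n: n*(n-1)/2 (triangular-number form)."""
    return n * (n - 1) // 2


def independent_distribution(
    params: ModelParams, construct: ConstructSpec
) -> StateDistribution:
    """Poisson-binomial state distribution over a construct's available sites."""
    p = construct.site_probabilities(params)
    poly = _poisson_binomial(p)
    return StateDistribution(tuple(poly / poly.sum()))


def cooperative_distribution(
    params: ModelParams, construct: ConstructSpec
) -> StateDistribution:
    """Cooperative state distribution: P(n) reweighted by c**(n(n-1)/2)."""
    p = construct.site_probabilities(params)
    base = _poisson_binomial(p)
    n = np.arange(base.size)
    weights = np.power(float(params.c), n * (n - 1) / 2.0)
    weighted = weights * base
    return StateDistribution(tuple(weighted / weighted.sum()))


def conditional_gain(dist: StateDistribution, n: int) -> float:
    """Conditional probability ratio P(n+1)/P(n) of gaining one palmitate.

    For the cooperative model this obeys the defining identity
    gain_coop(n) = c**n * gain_independent(n).
    """
    if not 0 <= n < dist.n_max:
        raise ValueError(f"state index {n} outside [0, {dist.n_max})")
    if dist.fractions[n] <= 0.0:
        raise ZeroDivisionError(f"P({n}) = 0; conditional gain undefined")
    return dist.fractions[n + 1] / dist.fractions[n]


def distribution_summary(dist: StateDistribution) -> Tuple[float, int]:
    """(mean state, mode state) — the average palmitoylation state read off
    integrated peak areas, and the most prevalent isoform."""
    return dist.mean_state(), dist.mode_state()
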