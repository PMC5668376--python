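"""Least-squares estimation of site probabilities and cooperativity.

Fits the independent (Poisson-binomial) or cooperative state model to
observed palmitoylation-state fractions across a panel of constructs
(wild type, multi-site and single-site Cys mutants, Cys-free variants).
The panel design is what makes the parameters identifiable: single-site
constructs pin the per-site probabilities, and constructs with two or more
sites carry the information about cooperativity.

The core is the scikit-learn style :class:`PalmitoylationEstimator`; the
module-level functions (:func:`fit_single_site`, :func:`predict_panel`,
:func:`fit_global`, :func:`staged_protocol`) are thin wrappers over it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .model import (
    ConstructSpec,
    ModelParams,
    SitePanel,
    StateDistribution,
    cooperative_distribution,
    independent_distribution,
)

__all__ = [
    "Observation",
    "FitResult",
    "StagedReport",
    "IdentifiabilityError",
    "PalmitoylationEstimator",
    "fit_single_site",
    "predict_panel",
    "r_squared",
    "fit_global",
    "staged_protocol",
]

logger = logging.getLogger(__name__)

#: Observed fractions may miss 1 by this much before being rejected;
#: within the slack they are renormalized with a logged warning.
FRACTION_SUM_SLACK = 0.02


class IdentifiabilityError(ValueError):
    """Raised when the requested parameters cannot be determined from the
    observed panel, e.g. fitting cooperativity when no construct exposes
    two or more palmitoylation sites simultaneously."""


@dataclass(frozen=True)
class Observation:
    """Observed state fractions for one construct and replicate."""

    construct_id: str
    replicate: str
    fractions: Tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.fractions, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("fractions must be a non-empty 1-D sequence")
        if (arr < 0).any():
            raise ValueError("observed fractions must be non-negative")
        total = arr.sum()
        if abs(total - 1.0) > FRACTION_SUM_SLACK:
            raise ValueError(
                f"fractions for {self.construct_id}/{self.replicate} sum to "
                f"{total:.4f}, outside 1 ± {FRACTION_SUM_SLACK}"
            )
        if abs(total - 1.0) > 1e-12:
            logger.warning(
                "renormalizing fractions of %s/%s (sum %.6f)",
                self.construct_id,
                self.replicate,
                total,
            )
            object.__setattr__(self, "fractions", tuple(arr / total))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit.

    ``fixed`` records parameters held constant during optimization (for
    example ``{"c": 1.24}`` when a cooperativity value is borrowed from a
    different protein).
    """

    params: ModelParams
    residuals: np.ndarray
    r_squared: float
    objective: float
    converged: bool
    model: str
    fixed: Dict[str, float] = field(default_factory=dict)
    n_eval: int = 0

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params.to_dict(),
            "fixed": dict(self.fixed),
            "r_squared": self.r_squared,
            "objective": self.objective,
            "converged": self.converged,
            "n_eval": self.n_eval,
            "residuals": [float(r) for r in self.residuals],
        }


def r_squared(
    observed: Sequence[float],
    predicted: Sequence[float],
    method: str = "determination",
) -> float:
    """Goodness of fit between pooled observed and predicted fractions.

    ``method="determination"`` (default) is the coefficient of
    determination 1 - SS_res/SS_tot; ``method="pearson"`` is the squared
    Pearson correlation. Both are exposed because summary correlations of
    predicted vs. observed distributions are reported either way in
    practice.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length 1-D, n >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero total variance: R^2 undefined")
    if method == "determination":
        ss_res = float(np.sum((obs - pred) ** 2))
        return 1.0 - ss_res / ss_tot
    if method == "pearson":
        r = np.corrcoef(obs, pred)[0, 1]
        return float(r * r)
    raise ValueError(f"unknown R^2 method {method!r}")


def _poly(p: np.ndarray) -> np.ndarray:
    poly = np.array([1.0])
    for pi in p:
        poly = np.convolve(poly, np.array([1.0 - pi, pi]))
    return poly


def _fractions(p: np.ndarray, c: float) -> np.ndarray:
    """Model fractions for raw parameter values (no [0,1] validation, so the
    optimizer may roam when the fit is unrestrained)."""
    base = _poly(p)
    if c != 1.0:
        n = np.arange(base.size)
        base = np.power(c, n * (n - 1) / 2.0) * base
    total = base.sum()
    if total <= 0 or not np.isfinite(total):
        return np.full(base.size, np.inf)
    return base / total


class PalmitoylationEstimator(BaseEstimator):
    """Least-squares fit of per-site probabilities and cooperativity.

    Parameters
    ----------
    model : {"cooperative", "independent"}
        "independent" holds c = 1; "cooperative" fits c unless ``fix_c``
        is given.
    fix_c : float, optional
        Hold the cooperativity at this value (e.g. borrow a value fitted
        on another protein).
    fixed_p : mapping site -> probability, optional
        Hold these site probabilities fixed; remaining sites are fitted.
    unrestrained : bool
        Free the probabilities from their [0, 1] box (c stays positive,
        which the model requires). Physically p outside [0, 1] is
        meaningless, but the option reproduces a fully unconstrained
        minimization; well-behaved data never leaves the box.
    n_restarts : int
        Number of random restarts added to the deterministic start
        (p = 0.5, c = 1); the best optimum is kept.
    random_state : int
        Seed for the restart draws.
    c_max : float
        Upper bound on c for the box-constrained fit.

    Attributes
    ----------
    panel_ : SitePanel
        Site ordering used for the parameter vector.
    params_ : ModelParams
        Fitted parameters (clipped into the valid domain if the
        unrestrained optimum strayed outside it).
    result_ : FitResult
        Full diagnostics: residuals, objective, R², convergence flag.
    """

    def __init__(
        self,
        model: str = "cooperative",
        fix_c: Optional[float] = None,
        fixed_p: Optional[Mapping[str, float]] = None,
        unrestrained: bool = False,
        n_restarts: int = 8,
        random_state: int = 0,
        c_max: float = 10.0,
        ftol: float = 1e-12,
        max_nfev: int = 10000,
    ) -> None:
        self.model = model
        self.fix_c = fix_c
        self.fixed_p = fixed_p
        self.unrestrained = unrestrained
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.c_max = c_max
        self.ftol = ftol
        self.max_nfev = max_nfev

    # ------------------------------------------------------------------

    def _validate(self, observations, constructs):
        if self.model not in ("independent", "cooperative"):
            raise ValueError(f"unknown model {self.model!r}")
        construct_map = _as_construct_map(constructs)
        observations = list(observations)
        if not observations:
            raise ValueError("no observations provided")
        for obs in observations:
            spec = construct_map.get(obs.construct_id)
            if spec is None:
                raise KeyError(f"no construct spec for {obs.construct_id!r}")
            if len(obs.fractions) != spec.n_max + 1:
                raise ValueError(
                    f"{obs.construct_id}/{obs.replicate}: {len(obs.fractions)} "
                    f"fractions for a construct with n_max = {spec.n_max}"
                )
        return observations, construct_map

    def fit(
        self,
        observations: Iterable[Observation],
        constructs: Iterable[ConstructSpec] | Mapping[str, ConstructSpec],
        panel: Optional[SitePanel] = None,
    ) -> "PalmitoylationEstimator":
        observations, construct_map = self._validate(observations, constructs)

        used_ids = {obs.construct_id for obs in observations}
        used_constructs = [construct_map[cid] for cid in construct_map if cid in used_ids]
        if panel is None:
            seen: List[str] = []
            for spec in used_constructs:
                for site in spec.sites:
                    if site not in seen:
                        seen.append(site)
            panel = SitePanel(tuple(seen))
        self.panel_ = panel

        fixed_p = dict(self.fixed_p or {})
        free_sites = [s for s in panel.sites if s not in fixed_p]
        fit_c = self.model == "cooperative" and self.fix_c is None
        if fit_c and not any(spec.n_max >= 2 for spec in used_constructs):
            raise IdentifiabilityError(
                "cooperativity cannot be derived from a panel with only "
                "single-available-site constructs"
            )
        if not free_sites and not fit_c:
            raise ValueError("no free parameters to fit")

        site_index = {s: i for i, s in enumerate(panel.sites)}
        free_index = {s: i for i, s in enumerate(free_sites)}
        n_free = len(free_sites)

        # Precompute per-observation construct site indices and targets.
        rows = []
        for obs in observations:
            spec = construct_map[obs.construct_id]
            idx = np.array([site_index[s] for s in spec.sites], dtype=int)
            rows.append((idx, obs.as_array()))

        p_full = np.empty(len(panel))
        for s, v in fixed_p.items():
            p_full[site_index[s]] = v

        c_fixed = 1.0 if self.model == "independent" else self.fix_c

        def residual(x: np.ndarray) -> np.ndarray:
            for s, j in free_index.items():
                p_full[site_index[s]] = x[j]
            c = x[n_free] if fit_c else c_fixed
            parts = [
                observed - _fractions(p_full[idx], c)
                for idx, observed in rows
            ]
            res = np.concatenate(parts) if parts else np.empty(0)
            return np.where(np.isfinite(res), res, 1e6)

        if self.unrestrained:
            lo = [-np.inf] * n_free
            hi = [np.inf] * n_free
        else:
            lo = [0.0] * n_free
            hi = [1.0] * n_free
        if fit_c:
            lo.append(1e-9)
            hi.append(np.inf if self.unrestrained else self.c_max)
        bounds = (np.array(lo), np.array(hi))

        rng = np.random.default_rng(self.random_state)
        starts = [np.array([0.5] * n_free + ([1.0] if fit_c else []))]
        for _ in range(self.n_restarts):
            start = rng.uniform(0.05, 0.95, size=n_free)
            if fit_c:
                start = np.append(start, rng.uniform(0.5, 2.0))
            starts.append(start)

        best = None
        n_eval = 0
        for x0 in starts:
            sol = least_squares(
                residual,
                x0,
                bounds=bounds,
                method="trf",
                ftol=self.ftol,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=self.max_nfev,
            )
            n_eval += sol.nfev
            if best is None or sol.cost < best.cost:
                best = sol

        assert best is not None
        x = best.x
        for s, j in free_index.items():
            p_full[site_index[s]] = x[j]
        c_hat = float(x[n_free]) if fit_c else float(c_fixed)

        self.p_raw_ = p_full.copy()
        self.c_raw_ = c_hat
        self.params_ = ModelParams(
            panel=panel,
            p=tuple(np.clip(p_full, 0.0, 1.0)),
            c=max(c_hat, 1e-12),
        )
        fixed: Dict[str, float] = dict(fixed_p)
        if self.model == "cooperative" and self.fix_c is not None:
            fixed["c"] = float(self.fix_c)

        predicted = np.concatenate(
            [_fractions(p_full[idx], c_hat) for idx, _ in rows]
        )
        observed = np.concatenate([observed for _, observed in rows])
        self.r_squared_ = r_squared(observed, predicted)
        self.result_ = FitResult(
            params=self.params_,
            residuals=best.fun.copy(),
            r_squared=self.r_squared_,
            objective=float(2.0 * best.cost),  # sum of squared residuals
            converged=bool(best.status > 0),
            model=self.model,
            fixed=fixed,
            n_eval=n_eval,
        )
        if not self.result_.converged:
            logger.warning("fit did not converge (status %d)", best.status)
        return self

    def predict(
        self, constructs: Iterable[ConstructSpec] | Mapping[str, ConstructSpec]
    ) -> Dict[str, StateDistribution]:
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted yet")
        return predict_panel(self.params_, constructs, model=self.model)

    def score(
        self,
        observations: Iterable[Observation],
        constructs: Iterable[ConstructSpec] | Mapping[str, ConstructSpec],
    ) -> float:
        """Pooled coefficient of determination of predicted vs. observed."""
        observations, construct_map = self._validate(list(observations), constructs)
        preds = self.predict(construct_map.values())
        obs_all, pred_all = [], []
        for obs in observations:
            obs_all.append(obs.as_array())
            pred_all.append(preds[obs.construct_id].as_array())
        return r_squared(np.concatenate(obs_all), np.concatenate(pred_all))


# ----------------------------------------------------------------------
# functional wrappers


def _as_construct_map(
    constructs: Iterable[ConstructSpec] | Mapping[str, ConstructSpec],
) -> Dict[str, ConstructSpec]:
    if isinstance(constructs, Mapping):
        return dict(constructs)
    out: Dict[str, ConstructSpec] = {}
    for spec in constructs:
        if spec.construct_id in out:
            raise ValueError(f"duplicate construct id {spec.construct_id!r}")
        out[spec.construct_id] = spec
    return out


def fit_single_site(
    observations: Iterable[Observation],
    constructs: Iterable[ConstructSpec] | Mapping[str, ConstructSpec],
) -> ModelParams:
    """Per-site probabilities from constructs with exactly one available site.

    For a single-site construct the palmitoylated fraction *is* the site
    probability, so p_i is the replicate-averaged fraction of state 1.
    Returns c = 1 parameters covering only the sites that have a
    single-site construct.
    """
    construct_map = _as_construct_map(constructs)
    per_site: Dict[str, List[float]] = {}
    order: List[str] = []
    for obs in observations:
        spec = construct_map.get(obs.construct_id)
        if spec is None:
            raise KeyError(f"no construct spec for {obs.construct_id!r}")
        if spec.n_max != 1:
            raise ValueError(
                f"construct {spec.construct_id!r} has {spec.n_max} available "
                "sites; single-site estimation requires exactly one"
            )
        if len(obs.fractions) != 2:
            raise ValueError(
                f"{obs.construct_id}/{obs.replicate}: expected 2 fractions"
            )
        site = spec.sites[0]
        if site not in per_site:
            per_site[site] = []
            order.append(site)
        per_site[site].append(obs.fractions[1])
    if not per_site:
        raise ValueError("no single-site observations provided")
    panel = SitePanel(tuple(order))
    p = tuple(float(np.mean(per_site[s])) for s in order)
    return ModelParams(panel=panel, p=p, c=1.0)


def predict_panel(
    params: ModelParams,
    constructs: Iterable[ConstructSpec] | Mapping[str, ConstructSpec],
    model: str = "independent",
) -> Dict[str, StateDistribution]:
    """State distribution per construct under the given model parameters."""
    construct_map = _as_construct_map(constructs)
    if model == "independent":
        func = independent_distribution
    elif model == "cooperative":
        func = cooperative_distribution
    else:
        raise ValueError(f"unknown model {model!r}")
    return {cid: func(params, spec) for cid, spec in construct_map.items()}


def fit_global(
    observations: Iterable[Observation],
    constructs: Iterable[ConstructSpec] | Mapping[str, ConstructSpec],
    model: str = "cooperative",
    panel: Optional[SitePanel] = None,
    fix_c: Optional[float] = None,
    fixed_p: Optional[Mapping[str, float]] = None,
    unrestrained: bool = False,
    n_restarts: int = 8,
    random_state: int = 0,
) -> FitResult:
    """Global least-squares fit; see :class:`PalmitoylationEstimator`."""
    est = PalmitoylationEstimator(
        model=model,
        fix_c=fix_c,
        fixed_p=fixed_p,
        unrestrained=unrestrained,
        n_restarts=n_restarts,
        random_state=random_state,
    )
    est.fit(observations, constructs, panel=panel)
    return est.result_


# ----------------------------------------------------------------------
# staged protocol


@dataclass
class StagedReport:
    """Four-stage analysis mirroring how the panel is interrogated:

    1. single-site priors from minimal constructs (independent model);
    2. independent-model prediction of the multi-site constructs;
    3. cooperative prediction with a borrowed or singly-fitted c;
    4. global cooperative fit of every parameter.
    """

    priors: ModelParams
    stages: List[dict]
    final: FitResult

    def to_dict(self) -> dict:
        return {
            "priors": self.priors.to_dict(),
            "stages": self.stages,
            "final": self.final.to_dict(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _background_sites(specs: Sequence[ConstructSpec]) -> set:
    """Sites present in every construct of the panel.

    A low-occupancy site introduced by the cloning strategy travels with
    every construct, including the nominal 'no-site' variant; treating such
    ubiquitous sites as background lets single-site constructs be
    recognized as 'one engineered site (+ background)'.
    """
    if not specs:
        return set()
    common = set(specs[0].sites)
    for spec in specs[1:]:
        common &= set(spec.sites)
    return common


def staged_protocol(
    observations: Iterable[Observation],
    constructs: Iterable[ConstructSpec] | Mapping[str, ConstructSpec],
    borrow_c: Optional[float] = None,
    single_site_ids: Optional[Sequence[str]] = None,
    n_restarts: int = 8,
    random_state: int = 0,
) -> StagedReport:
    """Run the staged single-site → independent → cooperative analysis."""
    observations = list(observations)
    construct_map = _as_construct_map(constructs)
    used = [
        construct_map[cid]
        for cid in construct_map
        if cid in {o.construct_id for o in observations}
    ]
    background = _background_sites(used)

    if single_site_ids is None:
        single_ids = {
            s.construct_id
            for s in used
            if len(set(s.sites) - background) <= 1
        }
    else:
        single_ids = set(single_site_ids)
    if not single_ids:
        raise ValueError("no single-site constructs identified in the panel")

    single_obs = [o for o in observations if o.construct_id in single_ids]
    multi_obs = [o for o in observations if o.construct_id not in single_ids]
    single_specs = {cid: construct_map[cid] for cid in single_ids}

    covered = set().union(*(set(s.sites) for s in single_specs.values()))
    all_sites = set().union(*(set(s.sites) for s in used))
    missing = all_sites - covered
    if missing:
        raise ValueError(
            f"sites {sorted(missing)} have no single-site construct; "
            "priors cannot be estimated"
        )
    panel_order = []
    for spec in used:
        for site in spec.sites:
            if site not in panel_order:
                panel_order.append(site)
    panel = SitePanel(tuple(panel_order))

    # Stage 1 — replicate-averaged single-site constructs, independent model.
    averaged = _average_replicates(single_obs)
    est1 = PalmitoylationEstimator(
        model="independent", n_restarts=n_restarts, random_state=random_state
    )
    est1.fit(averaged, single_specs, panel=SitePanel(
        tuple(s for s in panel.sites if s in covered)
    ))
    priors = est1.params_
    stages: List[dict] = [
        {
            "stage": 1,
            "label": "single-site priors",
            "params": priors.to_dict(),
            "r_squared": est1.r_squared_,
            "note": f"fit to constructs {sorted(single_ids)}",
        }
    ]

    multi_specs = {
        cid: construct_map[cid]
        for cid in construct_map
        if cid not in single_ids and cid in {o.construct_id for o in multi_obs}
    }

    # Stage 2 — independent-model prediction of multi-site constructs.
    r2_indep = None
    if multi_obs:
        preds = predict_panel(priors, multi_specs, model="independent")
        r2_indep = _pooled_r2(multi_obs, preds)
    stages.append(
        {
            "stage": 2,
            "label": "independent prediction",
            "r_squared": r2_indep,
            "params": priors.to_dict(),
        }
    )

    # Stage 3 — cooperative prediction: borrowed c, or c fitted alone.
    if borrow_c is not None:
        c3 = float(borrow_c)
        note3 = "borrowed c"
    else:
        est3 = PalmitoylationEstimator(
            model="cooperative",
            fixed_p={s: priors.probability(s) for s in priors.panel.sites},
            n_restarts=n_restarts,
            random_state=random_state,
        )
        est3.fit(multi_obs if multi_obs else observations, construct_map, panel=panel)
        c3 = est3.params_.c
        note3 = "fitted c"
    coop_params = ModelParams(panel=priors.panel, p=priors.p, c=c3)
    r2_coop = None
    if multi_obs:
        preds = predict_panel(coop_params, multi_specs, model="cooperative")
        r2_coop = _pooled_r2(multi_obs, preds)
    stages.append(
        {
            "stage": 3,
            "label": "cooperative prediction",
            "r_squared": r2_coop,
            "params": coop_params.to_dict(),
            "note": note3,
        }
    )

    # Stage 4 — global cooperative fit of all parameters to all data.
    est4 = PalmitoylationEstimator(
        model="cooperative", n_restarts=n_restarts, random_state=random_state
    )
    est4.fit(observations, construct_map, panel=panel)
    stages.append(
        {
            "stage": 4,
            "label": "global cooperative fit",
            "r_squared": est4.r_squared_,
            "params": est4.params_.to_dict(),
        }
    )
    logger.info(
        "staged protocol: R2 stages %s",
        [s.get("r_squared") for s in stages],
    )
    return StagedReport(priors=priors, stages=stages, final=est4.result_)


def _average_replicates(observations: Sequence[Observation]) -> List[Observation]:
    by_construct: Dict[str, List[np.ndarray]] = {}
    for obs in observations:
        by_construct.setdefault(obs.construct_id, []).append(obs.as_array())
    return [
        Observation(cid, "mean", tuple(np.mean(stack, axis=0)))
        for cid, stack in by_construct.items()
    ]


def _pooled_r2(
    observations: Sequence[Observation],
    predictions: Mapping[str, StateDistribution],
) -> float:
    obs_all = np.concatenate([o.as_array() for o in observations])
    pred_all = np.concatenate(
        [predictions[o.construct_id].as_array() for o in observations]
    )
    return r_squared(obs_all, pred_all)
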