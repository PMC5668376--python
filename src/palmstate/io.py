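"""Readers and writers for the pipeline's plain-text formats.

All tabular data are UTF-8 TSV with a header row; numbers use a decimal
point and are written at full double precision so write → read round trips
exactly. Model parameters, scenarios, and fit reports travel as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping

import numpy as np
import pandas as pd

from .fitting import FitResult, Observation, StagedReport
from .model import ConstructSpec, ModelParams, StateDistribution
from .spectra import MzSpectrum
from .synthetic import Scenario

__all__ = [
    "read_observations",
    "write_observations",
    "read_spectrum",
    "write_spectrum",
    "read_distributions",
    "write_distributions",
    "read_constructs",
    "write_constructs",
    "read_params",
    "write_params",
    "read_scenario",
    "write_scenario",
    "write_report",
]

_FLOAT = "%.17g"


def write_observations(
    observations: Iterable[Observation], path: str | Path
) -> None:
    rows = [
        {
            "construct_id": obs.construct_id,
            "replicate": obs.replicate,
            "n": n,
            "fraction": fraction,
        }
        for obs in observations
        for n, fraction in enumerate(obs.fractions)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def read_observations(path: str | Path) -> List[Observation]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"construct_id": str, "replicate": str})
    required = {"construct_id", "replicate", "n", "fraction"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    observations: List[Observation] = []
    for (cid, rep), group in frame.groupby(["construct_id", "replicate"], sort=False):
        group = group.sort_values("n")
        states = group["n"].to_numpy()
        if not np.array_equal(states, np.arange(states.size)):
            raise ValueError(
                f"{path}: states for {cid}/{rep} must be contiguous from 0"
            )
        observations.append(
            Observation(str(cid), str(rep), tuple(group["fraction"].to_numpy()))
        )
    return observations


def write_spectrum(spectrum: MzSpectrum, path: str | Path) -> None:
    pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT
    )


def read_spectrum(path: str | Path) -> MzSpectrum:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (position, intensity)")
    position = frame.iloc[:, 0].to_numpy(dtype=float)
    intensity = frame.iloc[:, 1].to_numpy(dtype=float)
    return MzSpectrum(mz=position, intensity=intensity)


def write_distributions(
    distributions: Mapping[str, StateDistribution], path: str | Path
) -> None:
    rows = [
        {"construct_id": cid, "n": n, "fraction": fraction}
        for cid, dist in distributions.items()
        for n, fraction in enumerate(dist.fractions)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def read_distributions(path: str | Path) -> Dict[str, StateDistribution]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"construct_id": str})
    out: Dict[str, StateDistribution] = {}
    for cid, group in frame.groupby("construct_id", sort=False):
        group = group.sort_values("n")
        out[str(cid)] = StateDistribution(tuple(group["fraction"].to_numpy()))
    return out


def write_constructs(
    constructs: Iterable[ConstructSpec], path: str | Path
) -> None:
    rows = [
        {"construct_id": spec.construct_id, "sites": ";".join(spec.sites)}
        for spec in constructs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_constructs(path: str | Path) -> List[ConstructSpec]:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype=str, keep_default_na=False)
    if not {"construct_id", "sites"} <= set(frame.columns):
        raise ValueError(f"{path}: expected columns construct_id, sites")
    out: List[ConstructSpec] = []
    for _, row in frame.iterrows():
        sites = tuple(s for s in str(row["sites"]).split(";") if s)
        out.append(ConstructSpec(str(row["construct_id"]), sites))
    return out


def write_params(params: ModelParams, path: str | Path) -> None:
    params.to_json(path)


def read_params(path: str | Path) -> ModelParams:
    return ModelParams.from_json(path)


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    Path(path).write_text(json.dumps(scenario.to_dict(), indent=2) + "\n")


def read_scenario(path: str | Path) -> Scenario:
    return Scenario.from_dict(json.loads(Path(path).read_text()))


def write_report(report: FitResult | StagedReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
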