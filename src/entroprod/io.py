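"""File formats, run configuration and the comparison harness.

CSV is the single tabular interchange format (time series of entropy
rates); JSON holds matrices, configs and run metadata.  Every CLI run
writes a metadata sidecar (config + seed + package version) from which
it can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .markov import RateMatrix, validate_rate_matrix

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "read_rate_matrix_csv",
    "write_rate_matrix_csv",
    "read_rate_matrix_json",
    "write_rate_matrix_json",
    "write_timeseries",
    "read_timeseries",
    "compare",
]

TIMESERIES_COLUMNS = ("time", "S", "Sdot", "Si", "Se", "Sia", "Sina")


class ConfigError(ValueError):
    """Invalid run configuration, with a path into the offending document."""


@dataclass
class RunConfig:
    """A fully specified, reproducible run.

    ``defaulted`` records which keys were filled with defaults at load
    time (provenance), and round-trips losslessly through JSON/YAML.
    """

    subcommand: str
    system: str
    params: dict = field(default_factory=dict)
    t_max: float = 5.0
    n_times: int = 51
    out: str | None = None
    seed: int = 0
    tol: float = 1e-8
    defaulted: list = field(default_factory=list)

    _DEFAULTS = {
        "params": dict,
        "t_max": 5.0,
        "n_times": 51,
        "out": None,
        "seed": 0,
        "tol": 1e-8,
    }

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_max, self.n_times)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration.

    Unknown keys are rejected with the list of valid keys; type
    mismatches report the path into the document.  Keys absent from the
    file are filled with defaults and recorded in ``defaulted``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ConfigError("config document must be a mapping")
    valid = {f.name for f in dataclasses.fields(RunConfig)} - {"defaulted"}
    unknown = set(raw) - valid - {"defaulted"}
    if unknown:
        raise ConfigError(
            f"unknown keys {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    for key in ("subcommand", "system"):
        if key not in raw:
            raise ConfigError(f"missing required key '{key}'")
        if not isinstance(raw[key], str):
            raise ConfigError(f"at .{key}: expected string, got {type(raw[key]).__name__}")
    checks = {"params": dict, "t_max": (int, float), "n_times": int,
              "seed": int, "tol": (int, float)}
    for key, typ in checks.items():
        if key in raw and not isinstance(raw[key], typ):
            raise ConfigError(
                f"at .{key}: expected {typ}, got {type(raw[key]).__name__}"
            )
    defaulted = [k for k in RunConfig._DEFAULTS if k not in raw]
    raw.pop("defaulted", None)
    return RunConfig(**raw, defaulted=defaulted)


def dump_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    doc = cfg.to_dict()
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))


# ---------------------------------------------------------------------------
# Rate-matrix formats
# ---------------------------------------------------------------------------

def read_rate_matrix_csv(path) -> RateMatrix:
    """Dense CSV with a header row of state labels."""
    df = pd.read_csv(path)
    return validate_rate_matrix(df.to_numpy(dtype=float),
                                labels=tuple(map(str, df.columns)))


def write_rate_matrix_csv(W: RateMatrix, path) -> None:
    pd.DataFrame(W.w, columns=list(W.labels)).to_csv(path, index=False)


def read_rate_matrix_json(path) -> RateMatrix:
    """JSON object ``{"labels": [...], "rates": [[...]]}``."""
    doc = json.loads(Path(path).read_text())
    return validate_rate_matrix(
        np.array(doc["rates"], dtype=float),
        labels=tuple(map(str, doc.get("labels", ()))),
    )


def write_rate_matrix_json(W: RateMatrix, path) -> None:
    Path(path).write_text(
        json.dumps({"labels": list(W.labels), "rates": W.w.tolist()}, indent=2)
    )


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------

def write_timeseries(times, probabilities, rates, path, labels=None,
                     metadata: dict | None = None) -> None:
    """CSV time series with a JSON metadata sidecar.

    Columns: ``time, p_<label>..., S, Sdot, Si, Se, Sia, Sina`` at full
    float precision (repr round-trip).  ``rates`` is a sequence of
    :class:`~entroprod.markov.EntropyRates`.  The sidecar at
    ``<path>.meta.json`` records the metadata plus the package version.
    """
    times = np.asarray(times, dtype=float)
    probabilities = np.asarray(probabilities, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(probabilities.shape[1])]
    data = {"time": times}
    for i, lab in enumerate(labels):
        data[f"p_{lab}"] = probabilities[:, i]
    data["S"] = [r.shannon for r in rates]
    data["Sdot"] = [r.sdot for r in rates]
    data["Si"] = [r.si for r in rates]
    data["Se"] = [r.se for r in rates]
    data["Sia"] = [r.sia for r in rates]
    data["Sina"] = [r.sina for r in rates]
    pd.DataFrame(data).to_csv(path, index=False, float_format=None)
    sidecar = dict(metadata or {})
    sidecar["package_version"] = __version__
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2))


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Comparison harness: analytic vs engine vs simulation
# ---------------------------------------------------------------------------

def compare(system: str, params: dict, times, seed: int = 0,
            n_paths: int = 0) -> pd.DataFrame:
    """Cross-check the closed-form, engine and simulation routes.

    Returns a table with columns ``t, si_analytic, si_engine, si_sim,
    si_sim_se, discrepancy``; routes a system lacks are ``NaN``.
    Simulation runs only when ``n_paths > 0`` and estimates the
    *stationary* production (one value, attached to the last row).
    """
    from . import catalogue, hybrid, simulate
    from .markov import entropy_rates, solve_master, stationary_distribution

    times = np.asarray(times, dtype=float)
    rows = []
    sim_est = sim_se = math.nan

    if system == "two_state":
        spec = catalogue.TwoStateSpec(**params)
        W = catalogue.two_state_rate_matrix(spec)
        P0 = np.array([spec.p, 1.0 - spec.p])
        traj = solve_master(W, P0, times)
        for t, P in zip(times, traj):
            si_a = catalogue.two_state_solution(spec, t).si
            si_e = entropy_rates(P, W).si
            rows.append((t, si_a, si_e))
    elif system == "three_state":
        W = catalogue.three_state_rate_matrix(params["alpha"], params["beta"])
        traj = solve_master(W, [1.0, 0.0, 0.0], times)
        for t, P in zip(times, traj):
            si_a = catalogue.three_state_solution(
                params["alpha"], params["beta"], t
            ).si
            rows.append((t, si_a, entropy_rates(P, W).si))
        if n_paths:
            paths = simulate.sample_jump_paths(W, stationary_distribution(W),
                                               max(times[-1], 10.0), n_paths, seed)
            sim_est, sim_se = simulate.medium_entropy_rate(paths, W)
    elif system == "ring_rw":
        spec = catalogue.LatticeRWSpec(**params)
        W = catalogue.cyclic_rate_matrix(spec.n_sites, spec.right, spec.left)
        P0 = np.zeros(spec.n_sites)
        P0[0] = 1.0
        traj = solve_master(W, P0, times)
        for t, P in zip(times, traj):
            si_a = catalogue.ring_rw_solution(spec, t)[1]
            rows.append((t, si_a, entropy_rates(P, W).si))
        if n_paths:
            paths = simulate.sample_jump_paths(W, stationary_distribution(W),
                                               max(times[-1], 10.0), n_paths, seed)
            sim_est, sim_se = simulate.medium_entropy_rate(paths, W)
    elif system == "rtp":
        si_a = hybrid.rtp_stationary_entropy(
            params["v1"], params["v2"], params["D"],
            params.get("alpha", 1.0), params.get("L", 1.0))
        rows.append((math.inf, si_a, math.nan))
        if n_paths:
            spec = hybrid.SwitchingSpec(
                v=(params["v1"], params["v2"]), D=params["D"],
                L=params.get("L", 1.0),
                alpha=validate_rate_matrix(
                    [[0.0, params.get("alpha", 1.0)],
                     [params.get("alpha", 1.0), 0.0]]),
            )
            paths = simulate.euler_maruyama(spec, dt=0.01, T=20.0,
                                            n_paths=n_paths, seed=seed)
            v = np.asarray(spec.v)
            sim_est, sim_se = simulate.stratonovich_medium_entropy(
                paths, lambda x, m: v[m], spec.D)
    else:
        raise ValueError(f"unknown system {system!r}")

    df = pd.DataFrame(rows, columns=["t", "si_analytic", "si_engine"])
    df["si_sim"] = math.nan
    df["si_sim_se"] = math.nan
    if not math.isnan(sim_est):
        df.loc[df.index[-1], "si_sim"] = sim_est
        df.loc[df.index[-1], "si_sim_se"] = sim_se
    df["discrepancy"] = (df["si_analytic"] - df["si_engine"]).abs()
    return df
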