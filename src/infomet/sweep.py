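"""Parameter-grid orchestration: simulate -> statistics -> cost -> channel
-> capacity/efficiency (-> population decoding) per (a_rec, P_ext) point.

The ``full`` profile reproduces the study grid (9 P_ext values x 10 a_rec
values, 31 stimuli, 10800 one-second trials of the 1000-neuron network) and
is cluster/overnight scale.  The ``desk`` profile runs the quarter-scale
network on a reduced grid and trial count so a sweep completes on one CPU
in minutes; a_rec values intended for the full network should be scaled by
~4 on the desk grid to probe a comparable recurrent drive per neuron (the
in-degree is 4x smaller).

Results are keyed by (a_rec, P_ext) in one HDF5 store; completed points are
skipped on rerun, so an interrupted sweep resumes where it stopped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import NetworkConfig
from .connectivity import build_connectivity
from .cost import activity_cost
from .decoding import decode_efficiency
from .information import capacity_cost, info_metabolic_efficiency
from .lownoise import efficiency_low_noise, fisher_curve
from .simulate import find_lambda_max, run_ensemble
from .statistics import discretized_gaussian_channel, fit_io_curve

__all__ = [
    "FULL_P_EXT",
    "FULL_A_REC",
    "TABLE_W_GRID",
    "SweepSpec",
    "run_sweep",
    "tabulate_capacity_cost",
]

# study grids (full profile)
FULL_P_EXT = (0.01, 0.02, 0.03, 0.05, 0.1, 0.2, 0.5, 0.8, 1.0)
FULL_A_REC = (0.0, 0.01, 0.02, 0.03, 0.05, 0.1, 0.2, 0.3, 0.5, 1.0)  # nS
# cost budgets for C(W) tables, ATP
TABLE_W_GRID = tuple(x * 1e12 for x in (2, 3, 4, 5, 6, 7, 8, 10, 12, 15))

_DESK_A_REC = (0.0, 0.4, 1.2)  # nS, 4x-scaled counterpart of {0, 0.1, 0.3}
_DESK_P_EXT = (0.1, 0.5, 1.0)


@dataclass
class SweepSpec:
    """What to run: grids, trial counts, stages and seeding."""

    a_rec_values: tuple = _DESK_A_REC
    P_ext_values: tuple = _DESK_P_EXT
    n_trials: int = 240
    n_stimuli: int = 16
    profile: str = "desk"  # "desk" | "full"
    base_seed: int = 0
    out: str | Path | None = None
    stages: tuple = ("simulate", "channel", "capacity")  # + "lownoise", "decode"
    W_grid: tuple = ()  # cost budgets for C(W); empty -> efficiency only
    n_dense: int = 1000
    decode_components: int = 50
    ba_tol: float = 1e-7

    @classmethod
    def full(cls, out, base_seed: int = 0) -> "SweepSpec":
        return cls(
            a_rec_values=FULL_A_REC,
            P_ext_values=FULL_P_EXT,
            n_trials=10800,
            n_stimuli=31,
            profile="full",
            base_seed=base_seed,
            out=out,
            W_grid=TABLE_W_GRID,
        )

    def validate(self) -> None:
        if not self.a_rec_values or not self.P_ext_values:
            raise ValueError("parameter grids must be nonempty")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")


def _point_key(a_rec: float, P_ext: float) -> str:
    return f"arec_{a_rec:g}__pext_{P_ext:g}"


def _run_point(config: NetworkConfig, spec: SweepSpec) -> dict:
    conn = build_connectivity(config, seed=spec.base_seed)
    lam_max = find_lambda_max(
        config, conn, trials_per_probe=3, base_seed=spec.base_seed
    )
    ens = run_ensemble(
        config,
        conn,
        lam_max,
        n_trials=spec.n_trials,
        n_stimuli=spec.n_stimuli,
        base_seed=spec.base_seed,
    )
    io = fit_io_curve(ens, n_dense=spec.n_dense)
    cost = activity_cost(ens, io, config)
    out = {"lambda_max": lam_max, "io": io, "cost": cost, "ensemble": ens}
    if "channel" in spec.stages or "capacity" in spec.stages:
        channel = discretized_gaussian_channel(io)
        out["channel"] = channel
    if "capacity" in spec.stages:
        eff = info_metabolic_efficiency(channel, cost.w, tol=spec.ba_tol)
        out["E"] = eff.efficiency
        out["W_star"] = eff.W_star
        C = []
        for W in spec.W_grid:
            if W < cost.w.min():
                C.append(np.nan)
            else:
                C.append(capacity_cost(channel, cost.w, float(W), tol=spec.ba_tol).capacity)
        out["C_of_W"] = np.asarray(C)
    if "lownoise" in spec.stages:
        J = fisher_curve(io)
        E_low, W_low, _ = efficiency_low_noise(channel, cost.w, J)
        out["E_lownoise"] = E_low
        out["W_lownoise"] = W_low
    if "decode" in spec.stages:
        w_knots = np.interp(ens.lambda_grid, cost.lambda_grid, cost.w)
        dec = decode_efficiency(
            ens,
            w_knots,
            n_components=spec.decode_components,
            base_seed=spec.base_seed,
        )
        out["E_decode"] = dec["E"]
        out["E_decode_unbiased"] = dec["E0"]
    return out


_SCALARS = (
    "lambda_max",
    "E",
    "W_star",
    "E_lownoise",
    "W_lownoise",
    "E_decode",
    "E_decode_unbiased",
)


def run_sweep(spec: SweepSpec, config: NetworkConfig | None = None) -> dict:
    """Run the pipeline on every (a_rec, P_ext) grid point.

    Returns {(a_rec, P_ext): result dict}.  With ``spec.out`` set, scalar
    results and C(W) rows are persisted to HDF5 and completed points are
    skipped on rerun (resume semantics); failed points are recorded and the
    sweep continues.
    """
    spec.validate()
    if config is None:
        config = NetworkConfig() if spec.profile == "full" else NetworkConfig.miniature()
    store = None
    if spec.out is not None:
        out_path = Path(spec.out)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        store = h5py.File(out_path, "a")
    results: dict = {}
    try:
        for P_ext in spec.P_ext_values:
            for a_rec in spec.a_rec_values:
                key = _point_key(a_rec, P_ext)
                if store is not None and key in store:
                    grp = store[key]
                    if grp.attrs.get("status") == "ok":
                        results[(a_rec, P_ext)] = {
                            name: grp.attrs[name] for name in _SCALARS if name in grp.attrs
                        }
                        if "C_of_W" in grp:
                            results[(a_rec, P_ext)]["C_of_W"] = grp["C_of_W"][()]
                        continue
                    del store[key]
                pt_config = config.replace(a_rec=a_rec, P_ext=P_ext)
                try:
                    res = _run_point(pt_config, spec)
                except Exception as err:  # record and continue per point
                    warnings.warn(
                        f"grid point a_rec={a_rec}, P_ext={P_ext} failed: {err}",
                        stacklevel=2,
                    )
                    if store is not None:
                        grp = store.create_group(key)
                        grp.attrs["status"] = f"error: {err}"
                    continue
                results[(a_rec, P_ext)] = res
                if store is not None:
                    grp = store.create_group(key)
                    grp.attrs["status"] = "ok"
                    grp.attrs["a_rec"] = a_rec
                    grp.attrs["P_ext"] = P_ext
                    grp.attrs["base_seed"] = spec.base_seed
                    for name in _SCALARS:
                        if name in res:
                            grp.attrs[name] = res[name]
                    if "C_of_W" in res:
                        grp.create_dataset("C_of_W", data=res["C_of_W"])
                        grp.create_dataset("W_grid", data=np.asarray(spec.W_grid))
                    store.flush()
    finally:
        if store is not None:
            store.close()
    return results


def tabulate_capacity_cost(
    results: dict | str | Path, W_values: tuple = TABLE_W_GRID
) -> pd.DataFrame:
    """P_ext rows x W columns of max-over-a_rec capacity-cost values (bits).

    Each cell is the maximum of C(W) over the available a_rec grid — the
    envelope over recurrence strengths.  Cells without coverage are NaN.
    ``results`` is the dict from :func:`run_sweep` or a path to its store.
    """
    if not isinstance(results, dict):
        out: dict = {}
        with h5py.File(results, "r") as store:
            for key in store:
                grp = store[key]
                if grp.attrs.get("status") != "ok" or "C_of_W" not in grp:
                    continue
                entry = {"C_of_W": grp["C_of_W"][()], "W_grid": grp["W_grid"][()]}
                out[(float(grp.attrs["a_rec"]), float(grp.attrs["P_ext"]))] = entry
        results = out
    p_ext_values = sorted({p for (_, p) in results})
    table = pd.DataFrame(index=p_ext_values, columns=list(W_values), dtype=float)
    table.index.name = "P_ext"
    for (a_rec, p_ext), res in results.items():
        if "C_of_W" not in res:
            continue
        W_grid = res.get("W_grid")
        if W_grid is None:
            W_grid = np.asarray(W_values)
        for W, C in zip(np.asarray(W_grid), np.asarray(res["C_of_W"])):
            matches = [w for w in W_values if np.isclose(w, W)]
            if not matches or np.isnan(C):
                continue
            col = matches[0]
            cur = table.loc[p_ext, col]
            if np.isnan(cur) or C > cur:
                table.loc[p_ext, col] = C
    return table
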