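"""HDF5/CSV persistence of ensembles, channels, cost curves and results."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import NetworkConfig
from .cost import CostCurve
from .simulate import TrialEnsemble
from .statistics import ChannelModel, IOCurve

__all__ = [
    "save_ensemble",
    "load_ensemble",
    "save_channel",
    "load_channel",
    "io_curve_frame",
    "cost_curve_frame",
    "low_noise_frame",
    "fisher_population_frame",
    "capacity_frame",
]


def _config_attrs(grp: h5py.Group, config: NetworkConfig) -> None:
    for key, val in config.to_dict().items():
        grp.attrs[f"config_{key}"] = val


def _config_from_attrs(grp: h5py.Group) -> NetworkConfig:
    kwargs = {}
    for key, val in grp.attrs.items():
        if key.startswith("config_"):
            name = key[len("config_") :]
            if isinstance(val, bytes):
                val = val.decode()
            if isinstance(val, np.generic):
                val = val.item()
            kwargs[name] = val
    return NetworkConfig(**kwargs)


def save_ensemble(target: str | Path | h5py.Group, ensemble: TrialEnsemble) -> None:
    """Write a trial ensemble: one group per stimulus with counts and the
    Na-current record, configuration and seeds as attributes."""
    own = not isinstance(target, h5py.Group)
    grp = h5py.File(target, "w") if own else target
    try:
        _config_attrs(grp, ensemble.config)
        grp.attrs["connectivity_seed"] = ensemble.connectivity_seed
        grp.attrs["base_seed"] = ensemble.base_seed
        grp.attrs["delta_T"] = ensemble.delta_T
        grp.create_dataset("lambda_grid", data=ensemble.lambda_grid)
        for s in range(ensemble.n_stimuli):
            sub = grp.create_group(f"stimulus_{s}")
            sub.create_dataset(
                "counts", data=ensemble.counts[s].astype(np.uint32), compression="gzip"
            )
            sub.create_dataset(
                "na_current", data=[ensemble.i_na_exc[s], ensemble.i_na_inh[s]]
            )
    finally:
        if own:
            grp.close()


def load_ensemble(source: str | Path | h5py.Group) -> TrialEnsemble:
    own = not isinstance(source, h5py.Group)
    grp = h5py.File(source, "r") if own else source
    try:
        lam = grp["lambda_grid"][()]
        S = lam.size
        counts = np.stack([grp[f"stimulus_{s}/counts"][()] for s in range(S)])
        na = np.stack([grp[f"stimulus_{s}/na_current"][()] for s in range(S)])
        return TrialEnsemble(
            lambda_grid=lam,
            counts=counts,
            i_na_exc=na[:, 0],
            i_na_inh=na[:, 1],
            config=_config_from_attrs(grp),
            connectivity_seed=int(grp.attrs["connectivity_seed"]),
            base_seed=int(grp.attrs["base_seed"]),
            delta_T=float(grp.attrs["delta_T"]),
        )
    finally:
        if own:
            grp.close()


def save_channel(
    target: str | Path | h5py.Group,
    channel: ChannelModel,
    cost: CostCurve | None = None,
) -> None:
    """Shared channel layout: lambda_grid, cond_pmf, outputs (+ cost group)."""
    own = not isinstance(target, h5py.Group)
    grp = h5py.File(target, "w") if own else target
    try:
        grp.create_dataset("lambda_grid", data=channel.lambda_grid)
        grp.create_dataset("cond_pmf", data=channel.cond_pmf, compression="gzip")
        grp.create_dataset("outputs", data=channel.outputs)
        grp.attrs["n_max"] = int(channel.outputs.max())
        grp.attrs["Delta_T"] = channel.delta_T
        if cost is not None:
            cg = grp.create_group("cost")
            cg.create_dataset("cost_atp", data=cost.w)
            cg.create_dataset("lambda_grid", data=cost.lambda_grid)
            bk = cg.create_group("breakdown")
            bk.create_dataset("external_ap", data=cost.external_ap)
            bk.create_dataset("evoked_ap", data=cost.evoked_ap)
            bk.create_dataset("synaptic", data=cost.synaptic)
            cg.attrs["delta_T"] = cost.delta_T
    finally:
        if own:
            grp.close()


def load_channel(
    source: str | Path | h5py.Group,
) -> tuple[ChannelModel, CostCurve | None]:
    own = not isinstance(source, h5py.Group)
    grp = h5py.File(source, "r") if own else source
    try:
        channel = ChannelModel(
            lambda_grid=grp["lambda_grid"][()],
            cond_pmf=grp["cond_pmf"][()],
            outputs=grp["outputs"][()],
            delta_T=float(grp.attrs.get("Delta_T", 1.0)),
        )
        cost = None
        if "cost" in grp:
            cg = grp["cost"]
            cost = CostCurve(
                lambda_grid=cg["lambda_grid"][()],
                w=cg["cost_atp"][()],
                external_ap=cg["breakdown/external_ap"][()],
                evoked_ap=cg["breakdown/evoked_ap"][()],
                synaptic=cg["breakdown/synaptic"][()],
                delta_T=float(cg.attrs.get("delta_T", 1.0)),
            )
        return channel, cost
    finally:
        if own:
            grp.close()


def low_noise_frame(sol, w: np.ndarray, J: np.ndarray) -> pd.DataFrame:
    """Tabulate a grid low-noise solution: stimulus, input probability,
    cost and Fisher information."""
    if sol.lam_grid is None:
        raise ValueError("only grid-based solutions can be tabulated")
    return pd.DataFrame(
        {"lambda_khz": sol.lam_grid, "p": sol.p, "w_atp": np.asarray(w), "fisher": np.asarray(J)}
    )


def fisher_population_frame(curve) -> pd.DataFrame:
    """Tabulate a population Fisher curve with its two terms."""
    return pd.DataFrame(
        {
            "lambda_khz": curve.lambda_grid,
            "J_pop": curve.J_pop,
            "term_mean": curve.term_mean,
            "term_cov": curve.term_cov,
        }
    )


def capacity_frame(result) -> pd.DataFrame:
    """Tabulate a capacity-cost curve; the efficiency-optimal budget W* is
    marked in a boolean column."""
    W = np.asarray(result.W_grid, dtype=float)
    marker = np.zeros(W.size, dtype=bool)
    if np.isfinite(result.W_star) and W.size:
        marker[int(np.argmin(np.abs(W - result.W_star)))] = True
    return pd.DataFrame(
        {"W_atp": W, "C_bits": result.C, "at_W_star": marker}
    )


def io_curve_frame(io: IOCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lambda_khz": io.lambda_grid,
            "mu_total": io.mu,
            "var_total": io.var,
            "rate_exc_hz": io.mu_exc,
            "rate_inh_hz": io.mu_inh,
        }
    )


def cost_curve_frame(cost: CostCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lambda_khz": cost.lambda_grid,
            "w_atp": cost.w,
            "external_ap": cost.external_ap,
            "evoked_ap": cost.evoked_ap,
            "synaptic": cost.synaptic,
        }
    )
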