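"""Hierarchical HDF5 run container for datasets, weights and null ensembles."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .beamformer import BeamformerConfig, CovarianceEstimate, GridWeights
from .core import SensorTimeSeries, VoxelGrid
from .spectral import FrequencyBand

__all__ = ["save_run", "load_run", "save_grid_weights", "load_grid_weights"]


def save_run(path, data: SensorTimeSeries, manifest: dict | None = None) -> None:
    """Store a sensor dataset with a JSON-style manifest in its attributes."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("sensor_data", data=data.data)
        ds.attrs["fs"] = data.fs
        fh.attrs["manifest"] = json.dumps(manifest or {}, default=str)


def load_run(path):
    with h5py.File(path, "r") as fh:
        data = SensorTimeSeries(fh["sensor_data"][()], float(fh["sensor_data"].attrs["fs"]))
        manifest = json.loads(fh.attrs.get("manifest", "{}"))
    return data, manifest


def _write_grid(group, grid: VoxelGrid) -> None:
    group.create_dataset("positions", data=grid.positions)
    group.create_dataset("mask", data=grid.mask)
    group.attrs["spacing_mm"] = grid.spacing_mm
    group.attrs["shape"] = np.asarray(grid.shape)
    group.attrs["origin"] = grid.origin


def _read_grid(group) -> VoxelGrid:
    return VoxelGrid(
        group["positions"][()],
        float(group.attrs["spacing_mm"]),
        tuple(int(x) for x in group.attrs["shape"]),
        np.asarray(group.attrs["origin"]),
        group["mask"][()],
    )


def save_grid_weights(path, gw: GridWeights, name: str = "weights") -> None:
    """Archive per-voxel weights, orientations and covariance for one band."""
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        g = fh.create_group(name)
        g.create_dataset("weights", data=gw.weights)
        g.create_dataset("deltas", data=gw.deltas)
        g.create_dataset("covariance", data=gw.covariance.C)
        if gw.lead_fields is not None:
            g.create_dataset("lead_fields", data=gw.lead_fields)
        g.attrs["sigma"] = gw.sigma
        g.attrs["cov_window"] = np.asarray(gw.covariance.window)
        g.attrs["cov_n_samples"] = gw.covariance.n_samples
        g.attrs["mu"] = gw.config.mu
        g.attrs["window_policy"] = gw.config.window_policy
        if gw.config.band is not None:
            g.attrs["band"] = json.dumps(
                [gw.config.band.name, gw.config.band.f_lo, gw.config.band.f_hi]
            )
        _write_grid(g.create_group("grid"), gw.grid)


def load_grid_weights(path, name: str = "weights") -> GridWeights:
    with h5py.File(path, "r") as fh:
        g = fh[name]
        band = None
        if "band" in g.attrs:
            nm, lo, hi = json.loads(g.attrs["band"])
            band = FrequencyBand(nm, lo, hi)
        cfg = BeamformerConfig(
            mu=float(g.attrs["mu"]), band=band, window_policy=str(g.attrs["window_policy"])
        )
        cov = CovarianceEstimate(
            g["covariance"][()],
            tuple(int(x) for x in g.attrs["cov_window"]),
            int(g.attrs["cov_n_samples"]),
        )
        lead_fields = g["lead_fields"][()] if "lead_fields" in g else None
        return GridWeights(
            g["weights"][()], g["deltas"][()], _read_grid(g["grid"]), cov,
            float(g.attrs["sigma"]), cfg, lead_fields,
        )
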