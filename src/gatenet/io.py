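"""HDF5 cohort/network containers and CSV exports."""

from __future__ import annotations

import io as io_mod
import json

import h5py
import numpy as np
import pandas as pd

from .erp import EpochSet
from .inverse import LeadField
from .synthgen import SynthCohort, SynthConfig

__all__ = ["save_cohort", "load_cohort", "save_networks", "load_networks"]


def save_cohort(cohort: SynthCohort, path: str) -> None:
    """Write epochs, lead field, atlas, covariates and truth to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = cohort.config.fs
        f.attrs["s2_offset_ms"] = cohort.config.s2_offset_ms
        f.attrs["labels"] = json.dumps(cohort.labels)
        f.attrs["subjects"] = json.dumps(cohort.subjects)
        f.attrs["vertex_channels"] = json.dumps(cohort.vertex_channels)
        f.attrs["seed"] = cohort.config.seed
        f.create_dataset("lead_field/gain", data=cohort.lead_field.gain)
        f.attrs["sensor_names"] = json.dumps(cohort.lead_field.sensor_names)
        atlas = f.create_group("atlas")
        atlas.create_dataset("roi", data=cohort.atlas["roi"].to_numpy())
        atlas.create_dataset("centroid_source", data=cohort.atlas["centroid_source"].to_numpy())
        atlas.attrs["name"] = json.dumps(list(cohort.atlas["name"]))
        atlas.attrs["hemisphere"] = json.dumps(list(cohort.atlas["hemisphere"]))
        ep = f.create_group("epochs")
        for e in cohort.epochs:
            d = ep.create_dataset(e.subject, data=e.data, compression="gzip", compression_opts=1)
            d.attrs["t0_idx"] = e.t0_idx
        f.attrs["covariates"] = cohort.covariates.to_json(orient="records")
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in cohort.truth.items()
        }
        truth["planted_edges"] = [[i, j, s] for i, j, s in truth["planted_edges"]]
        truth["auditory_rois"] = list(truth["auditory_rois"])
        f.attrs["truth"] = json.dumps(truth)


def load_cohort(path: str) -> SynthCohort:
    """Read a cohort container written by :func:`save_cohort`."""
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["fs"])
        s2_off = float(f.attrs["s2_offset_ms"])
        labels = json.loads(f.attrs["labels"])
        sensor_names = json.loads(f.attrs["sensor_names"])
        lead_field = LeadField(gain=f["lead_field/gain"][()], sensor_names=sensor_names)
        atlas = pd.DataFrame(
            {
                "roi": f["atlas/roi"][()],
                "name": json.loads(f["atlas"].attrs["name"]),
                "hemisphere": json.loads(f["atlas"].attrs["hemisphere"]),
                "centroid_source": f["atlas/centroid_source"][()],
            }
        )
        epochs = []
        for subject in json.loads(f.attrs["subjects"]):
            d = f["epochs"][subject]
            epochs.append(
                EpochSet(
                    data=d[()],
                    fs=fs,
                    t0_idx=int(d.attrs["t0_idx"]),
                    s2_offset_ms=s2_off,
                    ch_names=list(sensor_names),
                    subject=subject,
                )
            )
        covariates = pd.read_json(io_mod.StringIO(f.attrs["covariates"]), orient="records")
        truth = json.loads(f.attrs["truth"])
        truth["s1_amp_true"] = np.asarray(truth["s1_amp_true"])
        truth["s2_amp_true"] = np.asarray(truth["s2_amp_true"])
        truth["planted_edges"] = [(i, j, s) for i, j, s in truth["planted_edges"]]
        truth["auditory_rois"] = tuple(truth["auditory_rois"])
        config = SynthConfig(fs=fs, s2_offset_ms=s2_off, seed=int(f.attrs["seed"]))
    return SynthCohort(
        epochs=epochs,
        lead_field=lead_field,
        atlas=atlas,
        labels=labels,
        covariates=covariates,
        truth=truth,
        config=config,
    )


def save_networks(networks: dict, subjects: list[str], path: str) -> None:
    """Write the per-condition ``subjects x n x n`` network stacks."""
    with h5py.File(path, "w") as f:
        f.attrs["subjects"] = json.dumps(list(subjects))
        for cond, stack in networks.items():
            f.create_dataset(cond.replace("/", "_"), data=np.asarray(stack))


def load_networks(path: str) -> tuple[dict, list[str]]:
    with h5py.File(path, "r") as f:
        subjects = json.loads(f.attrs["subjects"])
        networks = {k: f[k][()] for k in f}
    return networks, subjects
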