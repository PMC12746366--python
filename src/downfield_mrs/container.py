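"""Spectra container: lossless storage of multi-channel FID cohorts.

Primary dialect is HDF5 (via h5py) with the layout::

    /schema_version                      (root attribute)
    /subjects/<id>/<experiment>/<TS_ms>/fid   complex dataset [channel x time]
                                       + attrs: dwell_time_s,
                                         transmitter_freq_mhz,
                                         reference_shift_ppm, TS_ms, TR_ms,
                                         TE_ms, NEX, experiment

``m0`` and ``water_ref`` scans live under a single pseudo-TS group.  A
plain-directory dialect (JSON metadata + CSV real/imag sample tables) is
provided for zero-dependency inspection and text-only archiving; both
round-trip bit-exactly for the complex samples and attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .fid import FidSeries
from .synthetic import SubjectDataset

__all__ = ["SCHEMA_VERSION", "write_container", "read_container"]

SCHEMA_VERSION = "downfield-mrs/1"

_REQUIRED_ATTRS = (
    "dwell_time_s",
    "transmitter_freq_mhz",
    "reference_shift_ppm",
    "experiment",
)
_META_ATTRS = ("TS_ms", "TR_ms", "TE_ms", "NEX")


def _fid_attrs(fid: FidSeries, experiment: str) -> dict:
    attrs = {
        "dwell_time_s": float(fid.dwell_time),
        "transmitter_freq_mhz": float(fid.transmitter_freq),
        "reference_shift_ppm": float(fid.reference_shift),
        "experiment": experiment,
    }
    meta_map = {"TS_ms": "TS", "TR_ms": "TR", "TE_ms": "TE", "NEX": "NEX"}
    for attr, key in meta_map.items():
        if key in fid.meta:
            attrs[attr] = float(fid.meta[key])
    return attrs


def _fid_from(samples: np.ndarray, attrs: dict) -> FidSeries:
    for name in _REQUIRED_ATTRS:
        if name not in attrs:
            raise ValueError(f"container scan missing required attribute {name!r}")
    meta = {"experiment": attrs["experiment"]}
    meta_map = {"TS_ms": "TS", "TR_ms": "TR", "TE_ms": "TE", "NEX": "NEX"}
    for attr, key in meta_map.items():
        if attr in attrs:
            meta[key] = float(attrs[attr])
    return FidSeries(
        samples=np.asarray(samples, dtype=complex),
        dwell_time=float(attrs["dwell_time_s"]),
        transmitter_freq=float(attrs["transmitter_freq_mhz"]),
        reference_shift=float(attrs["reference_shift_ppm"]),
        meta=meta,
    )


def _iter_scans(ds: SubjectDataset):
    for ts, fid in ds.selective.items():
        yield "selective", float(ts), fid
    for ts, fid in ds.broadband.items():
        yield "broadband", float(ts), fid
    yield "m0", float(ds.m0.meta.get("TS", 10000.0)), ds.m0
    yield "water_ref", 0.0, ds.water_ref


def write_container(
    datasets: list[SubjectDataset], path: str | Path, fmt: str = "hdf5"
) -> Path:
    """Write a cohort of subject datasets; returns the written path."""
    path = Path(path)
    if fmt == "hdf5":
        with h5py.File(path, "w") as h5:
            h5.attrs["schema_version"] = SCHEMA_VERSION
            root = h5.create_group("subjects")
            for ds in datasets:
                subj = root.create_group(ds.subject_id)
                for experiment, ts, fid in _iter_scans(ds):
                    grp = subj.create_group(f"{experiment}/{ts:g}")
                    dset = grp.create_dataset("fid", data=fid.samples)
                    for k, v in _fid_attrs(fid, experiment).items():
                        dset.attrs[k] = v
        return path
    if fmt == "dir":
        path.mkdir(parents=True, exist_ok=True)
        manifest = {"schema_version": SCHEMA_VERSION, "subjects": {}}
        for ds in datasets:
            entries = []
            for experiment, ts, fid in _iter_scans(ds):
                stem = f"{ds.subject_id}_{experiment}_{ts:g}"
                np.savetxt(
                    path / f"{stem}.csv",
                    np.column_stack([fid.samples.real.T, fid.samples.imag.T]),
                    delimiter=",",
                )
                entries.append(
                    {"file": f"{stem}.csv", "n_channels": fid.n_channels,
                     **_fid_attrs(fid, experiment)}
                )
            manifest["subjects"][ds.subject_id] = entries
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return path
    raise ValueError(f"unknown container format {fmt!r}")


def read_container(path: str | Path) -> list[SubjectDataset]:
    """Read a cohort container (either dialect); schema version is checked."""
    path = Path(path)
    if path.is_dir():
        return _read_dir(path)
    datasets = []
    with h5py.File(path, "r") as h5:
        version = h5.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(f"unknown container schema version {version!r}")
        for sid, subj in h5["subjects"].items():
            ds = SubjectDataset(selective={}, broadband={}, m0=None,
                                water_ref=None, subject_id=sid)
            for experiment, by_ts in subj.items():
                for ts_key, grp in by_ts.items():
                    dset = grp["fid"]
                    fid = _fid_from(dset[()], dict(dset.attrs))
                    if experiment == "selective":
                        ds.selective[float(ts_key)] = fid
                    elif experiment == "broadband":
                        ds.broadband[float(ts_key)] = fid
                    elif experiment == "m0":
                        ds.m0 = fid
                    elif experiment == "water_ref":
                        ds.water_ref = fid
            datasets.append(ds)
    datasets.sort(key=lambda d: d.subject_id)
    return datasets


def _read_dir(path: Path) -> list[SubjectDataset]:
    manifest = json.loads((path / "manifest.json").read_text())
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unknown container schema version {version!r}")
    datasets = []
    for sid, entries in manifest["subjects"].items():
        ds = SubjectDataset(selective={}, broadband={}, m0=None,
                            water_ref=None, subject_id=sid)
        for entry in entries:
            table = np.loadtxt(path / entry["file"], delimiter=",", ndmin=2)
            nch = entry["n_channels"]
            samples = (table[:, :nch] + 1j * table[:, nch:]).T
            fid = _fid_from(samples, entry)
            experiment = entry["experiment"]
            ts = float(entry.get("TS_ms", 0.0))
            if experiment == "selective":
                ds.selective[ts] = fid
            elif experiment == "broadband":
                ds.broadband[ts] = fid
            elif experiment == "m0":
                ds.m0 = fid
            elif experiment == "water_ref":
                ds.water_ref = fid
        datasets.append(ds)
    datasets.sort(key=lambda d: d.subject_id)
    return datasets
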