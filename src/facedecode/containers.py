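"""HDF5 containers for cohorts, decoding results, and RDM series.

One file per object; arrays round-trip bit-exactly and tabular metadata is
stored as JSON documents alongside.  Files carry a schema version attribute
and loading a file with a different (or absent) version raises a
:class:`SchemaError` rather than guessing.
"""

from __future__ import annotations

import io as _io
import json

import h5py
import numpy as np
import pandas as pd

from .decode import DecodingResult, SchemeSpec
from .montage import ChannelLayout
from .preprocess import PseudoTrialSet
from .rsa import RDMSeries
from .synth import EpochsCollection

SCHEMA_VERSION = 1


class SchemaError(IOError):
    """Raised for unreadable, truncated, or version-mismatched containers."""


def _open(path, kind: str) -> h5py.File:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SchemaError(f"cannot open {path}: {exc}") from exc
    v = f.attrs.get("schema_version")
    if v != SCHEMA_VERSION:
        f.close()
        raise SchemaError(
            f"{path}: schema version {v!r} != {SCHEMA_VERSION}; migrate the file")
    if f.attrs.get("kind") != kind:
        found = f.attrs.get("kind")
        f.close()
        raise SchemaError(f"{path}: expected a {kind} container, found {found!r}")
    return f


def _df_to_json(df: pd.DataFrame) -> str:
    return df.to_json(orient="table", index=False)


def _df_from_json(s: str) -> pd.DataFrame:
    return pd.read_json(_io.StringIO(s), orient="table")


def _write_layout(f: h5py.File, layout: ChannelLayout) -> None:
    g = f.create_group("layout")
    g.create_dataset("names", data=np.array(layout.names, dtype="S32"))
    g.create_dataset("pos3d", data=layout.pos3d)
    g.create_dataset("pos2d", data=layout.pos2d)


def _read_layout(f: h5py.File) -> ChannelLayout:
    g = f["layout"]
    names = tuple(n.decode() for n in g["names"][()])
    return ChannelLayout(names=names, pos3d=g["pos3d"][()], pos2d=g["pos2d"][()])


# -- epochs / pseudo-trials -------------------------------------------------

def save_epochs(path, epochs: EpochsCollection) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "epochs"
        f.attrs["sfreq"] = epochs.sfreq
        f.create_dataset("times", data=epochs.times)
        _write_layout(f, epochs.layout)
        for p, (x, md) in enumerate(zip(epochs.data, epochs.metadata)):
            g = f.create_group(f"participant_{p:03d}")
            g.create_dataset("data", data=x)
            g.attrs["metadata_json"] = _df_to_json(md)


def load_epochs(path) -> EpochsCollection:
    with _open(path, "epochs") as f:
        times = f["times"][()]
        layout = _read_layout(f)
        data, metadata = [], []
        for key in sorted(k for k in f if k.startswith("participant_")):
            data.append(f[key]["data"][()])
            metadata.append(_df_from_json(f[key].attrs["metadata_json"]))
        return EpochsCollection(data=data, metadata=metadata, times=times,
                                sfreq=float(f.attrs["sfreq"]), layout=layout)


def save_pseudo(path, pseudo: PseudoTrialSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "pseudo"
        f.attrs["sfreq"] = pseudo.sfreq
        f.attrs["bin_size"] = pseudo.bin_size
        f.create_dataset("times", data=pseudo.times)
        _write_layout(f, pseudo.layout)
        for p, (x, md) in enumerate(zip(pseudo.data, pseudo.metadata)):
            g = f.create_group(f"participant_{p:03d}")
            g.create_dataset("data", data=x)
            g.attrs["metadata_json"] = _df_to_json(md)


def load_pseudo(path) -> PseudoTrialSet:
    with _open(path, "pseudo") as f:
        times = f["times"][()]
        layout = _read_layout(f)
        data, metadata = [], []
        for key in sorted(k for k in f if k.startswith("participant_")):
            data.append(f[key]["data"][()])
            metadata.append(_df_from_json(f[key].attrs["metadata_json"]))
        return PseudoTrialSet(data=data, metadata=metadata, times=times,
                              sfreq=float(f.attrs["sfreq"]), layout=layout,
                              bin_size=int(f.attrs["bin_size"]))


# -- decoding results -------------------------------------------------------

def save_decoding(path, result: DecodingResult) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "decoding"
        f.attrs["scheme_json"] = json.dumps(
            {"target": result.scheme.target, "pair": result.scheme.pair})
        f.attrs["chance"] = result.chance
        f.attrs["folds_json"] = json.dumps(result.folds)
        f.attrs["meta_json"] = json.dumps(result.meta)
        f.create_dataset("accuracy", data=result.accuracy)
        f.create_dataset("times_ms", data=result.times_ms)
        if result.ch_names is not None:
            f.create_dataset("ch_names", data=np.array(result.ch_names, dtype="S32"))


def load_decoding(path) -> DecodingResult:
    with _open(path, "decoding") as f:
        sj = json.loads(f.attrs["scheme_json"])
        pair = tuple(sj["pair"]) if sj["pair"] else None
        ch = [n.decode() for n in f["ch_names"][()]] if "ch_names" in f else None
        return DecodingResult(
            accuracy=f["accuracy"][()],
            scheme=SchemeSpec(target=sj["target"], pair=pair),
            chance=float(f.attrs["chance"]), times_ms=f["times_ms"][()],
            folds=json.loads(f.attrs["folds_json"]),
            ch_names=ch, meta=json.loads(f.attrs["meta_json"]))


# -- RDM series -------------------------------------------------------------

def save_rdm_series(path, rdm: RDMSeries) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "rdm_series"
        f.attrs["stimulus_order_json"] = json.dumps(rdm.stimulus_order)
        f.create_dataset("values", data=rdm.values)
        f.create_dataset("times_ms", data=rdm.times_ms)


def load_rdm_series(path) -> RDMSeries:
    with _open(path, "rdm_series") as f:
        return RDMSeries(values=f["values"][()],
                         stimulus_order=json.loads(f.attrs["stimulus_order_json"]),
                         times_ms=f["times_ms"][()])
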