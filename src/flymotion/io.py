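"""File formats: multi-page TIFF movies, HDF5 trace/STRF containers, CSV tables."""
from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .segmentation import ROICluster
from .strf import STRF
from .synth import SYNAPSE_TABLE_COLUMNS, TernaryNoise

__all__ = [
    "save_movie_tiff", "load_movie_tiff",
    "save_traces_hdf5", "load_traces_hdf5",
    "save_noise_hdf5", "load_noise_hdf5",
    "save_strfs_hdf5", "load_strfs_hdf5",
    "save_cluster_masks", "load_cluster_table",
    "save_synapse_table", "load_synapse_table",
]

_EPOCH_COLS = ["onset_s", "offset_s", "kind", "direction", "contrast", "repeat"]


def save_movie_tiff(path, frames: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(frames, np.float32),
                     photometric="minisblack")


def load_movie_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def _write_epochs(h: h5py.Group, epochs: pd.DataFrame) -> None:
    g = h.create_group("epochs")
    for col in epochs.columns:
        data = epochs[col].to_numpy()
        if data.dtype == object:
            data = data.astype("S")
        g.create_dataset(col, data=data)


def _read_epochs(h: h5py.Group) -> pd.DataFrame | None:
    if "epochs" not in h:
        return None
    g = h["epochs"]
    out = {}
    for col in g:
        arr = g[col][()]
        if arr.dtype.kind == "S":
            arr = arr.astype(str)
        out[col] = arr
    return pd.DataFrame(out)


def save_traces_hdf5(path, traces: np.ndarray, rate: float,
                     epochs: pd.DataFrame | None = None,
                     t0: float = 0.0) -> None:
    """Trace container: /traces [n x T], /time [T], optional /epochs table."""
    traces = np.atleast_2d(np.asarray(traces, float))
    with h5py.File(str(path), "w") as h:
        h.create_dataset("traces", data=traces)
        h.create_dataset(
            "time", data=t0 + np.arange(traces.shape[1]) / rate
        )
        h.attrs["rate"] = rate
        if epochs is not None:
            _write_epochs(h, epochs)


def load_traces_hdf5(path):
    with h5py.File(str(path), "r") as h:
        return (h["traces"][()], float(h.attrs["rate"]), _read_epochs(h))


def save_noise_hdf5(path, noise: TernaryNoise) -> None:
    with h5py.File(str(path), "w") as h:
        d = h.create_dataset("values", data=noise.values)
        d.attrs["update_rate"] = noise.update_rate
        d.attrs["orientation"] = noise.orientation
        d.attrs["bar_size"] = noise.bar_size


def load_noise_hdf5(path) -> TernaryNoise:
    with h5py.File(str(path), "r") as h:
        d = h["values"]
        return TernaryNoise(
            d[()], float(d.attrs["update_rate"]), str(d.attrs["orientation"]),
            tuple(d.attrs["bar_size"]),
        )


def save_strfs_hdf5(path, strfs: list[STRF]) -> None:
    """STRF container: /strf/weights [n x lags x bars], /strf/r2 [n]."""
    with h5py.File(str(path), "w") as h:
        g = h.create_group("strf")
        g.create_dataset(
            "weights", data=np.stack([s.weights for s in strfs])
        )
        g.create_dataset(
            "r2", data=np.array([np.nan if s.r2 is None else s.r2
                                 for s in strfs])
        )
        g.attrs["lag_step"] = strfs[0].lag_step
        g.attrs["orientation"] = strfs[0].orientation
        ids = [s.cell_id or f"cell_{i:03d}" for i, s in enumerate(strfs)]
        g.create_dataset("cell_id", data=np.array(ids, dtype="S"))


def load_strfs_hdf5(path) -> list[STRF]:
    with h5py.File(str(path), "r") as h:
        g = h["strf"]
        W = g["weights"][()]
        r2 = g["r2"][()]
        ids = g["cell_id"][()].astype(str)
        return [
            STRF(W[i], float(g.attrs["lag_step"]),
                 str(g.attrs["orientation"]),
                 None if np.isnan(r2[i]) else float(r2[i]), ids[i])
            for i in range(len(W))
        ]


def save_cluster_masks(
    tiff_path, csv_path, clusters: list[ROICluster], shape: tuple[int, int]
) -> None:
    """Labeled mask image (cluster index + 1) plus a (cluster_id, x, y) table."""
    label = np.zeros(shape, np.uint16)
    rows = []
    for i, c in enumerate(clusters):
        label[c.pixels[:, 0], c.pixels[:, 1]] = i + 1
        for r, x in c.pixels:
            rows.append(dict(cluster_id=c.cluster_id, x=int(x), y=int(r)))
    tifffile.imwrite(str(tiff_path), label)
    pd.DataFrame(rows, columns=["cluster_id", "x", "y"]).to_csv(
        csv_path, index=False
    )


def load_cluster_table(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)


def save_synapse_table(path, table: pd.DataFrame) -> None:
    table[SYNAPSE_TABLE_COLUMNS].to_csv(path, index=False)


def load_synapse_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in SYNAPSE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"{path}: synapse table missing columns {missing}; header must be "
            + ",".join(SYNAPSE_TABLE_COLUMNS)
        )
    return table


def save_epochs_csv(path, epochs: pd.DataFrame) -> None:
    epochs.to_csv(path, index=False)


def load_epochs_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
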