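"""File formats: model JSON, raster MTX + JSON sidecar, epochs CSV, traces CSV."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csc_matrix

from .activity import PopulationTrace
from .ising import IsingModel, SpikeRaster
from .meanfield import MeanFieldModel
from .stimulation import StimEpochs

__all__ = [
    "save_model",
    "load_model",
    "save_raster",
    "load_raster",
    "save_meanfield",
    "load_meanfield",
    "save_epochs",
    "load_epochs",
    "save_trace",
    "load_trace",
]


def save_model(model: IsingModel, path) -> None:
    """Model as JSON {h, J, side}; floats via repr, lossless round trip."""
    payload = {
        "h": model.h.tolist(),
        "J": model.J.tolist(),
        "side": None if model.side is None else model.side.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> IsingModel:
    d = json.loads(Path(path).read_text())
    return IsingModel(np.asarray(d["h"]), np.asarray(d["J"]), side=d["side"])


def save_raster(raster: SpikeRaster, path) -> None:
    """Sparse Matrix Market file plus a .json sidecar with the metadata."""
    path = Path(path)
    mmwrite(str(path), csc_matrix(raster.activity))
    sidecar = {
        "dt": raster.dt,
        "side": None if raster.side is None else raster.side.tolist(),
        "positions": None if raster.positions is None else raster.positions.tolist(),
        "frame_rate": raster.frame_rate,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_raster(path) -> SpikeRaster:
    path = Path(path)
    act = np.asarray(mmread(str(path)).todense())
    meta = json.loads(path.with_suffix(".json").read_text())
    return SpikeRaster(
        act,
        dt=meta["dt"],
        side=meta["side"],
        positions=meta["positions"],
    )


def save_meanfield(mf: MeanFieldModel, path) -> None:
    d = {k: getattr(mf, k) for k in ("HL", "HR", "JL", "JR", "KL", "KR", "I")}
    Path(path).write_text(json.dumps(d))


def load_meanfield(path) -> MeanFieldModel:
    return MeanFieldModel(**json.loads(Path(path).read_text()))


def save_epochs(epochs: StimEpochs, path, dt: float) -> None:
    """Epochs as CSV with start_s, end_s, side columns."""
    rows = [
        {"start_s": s * dt, "end_s": e * dt, "side": side}
        for s, e, side in epochs.epochs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_epochs(path, dt: float) -> StimEpochs:
    df = pd.read_csv(path)
    eps = [
        (int(round(r.start_s / dt)), int(round(r.end_s / dt)), r.side)
        for r in df.itertuples()
    ]
    return StimEpochs(eps)


def save_trace(trace: PopulationTrace, path) -> None:
    t = np.arange(trace.n_bins) * trace.dt
    pd.DataFrame({"time_s": t, "mL": trace.mL, "mR": trace.mR}).to_csv(
        path, index=False
    )


def load_trace(path) -> PopulationTrace:
    df = pd.read_csv(path)
    dt = float(df.time_s.iloc[1] - df.time_s.iloc[0])
    return PopulationTrace(df.mL.to_numpy(), df.mR.to_numpy(), dt)
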