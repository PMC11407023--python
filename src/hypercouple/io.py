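"""On-disk formats.

* TrialTable: RFC-4180 CSV, UTF-8, "." decimal, fixed column order.
* Dyad epochs: HDF5 with datasets /player1/data and /player2/data
  [trials, channels, samples] float32 and attributes sfreq, tmin,
  channel_labels (plus per-player trial_indices when a subset was generated).
* TFRSet: HDF5 /power [trials, channels, freqs, times] float32 + /mask, axis
  attributes.
* CouplingMap: HDF5 /z and /rho [channels, freqs, times] + attributes.
* SensorLayout: whitespace-delimited text "label x y z".
* ClusterResult / RegressionResult: JSON via their to_dict().
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .coupling import CouplingMap
from .errors import FormatError
from .synth import EpochSet, SensorLayout
from .tfr import TFRSet

TRIAL_COLUMNS = ["pair_id", "trial_index", "block", "condition",
                 "rt1", "rt2", "delta", "abs_delta", "outcome"]


def _labels(attr) -> tuple[str, ...]:
    return tuple(s.decode() if isinstance(s, bytes) else str(s) for s in attr)


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------

def write_trials(path: str | Path, trials: pd.DataFrame) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial table is missing columns: {missing}")
    return df[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

def write_dyad_epochs(path: str | Path, ep1: EpochSet, ep2: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        for ep in (ep1, ep2):
            g = f.create_group(f"player{ep.player_id}")
            g.create_dataset("data", data=ep.data.astype(np.float32))
            g.attrs["sfreq"] = ep.sfreq
            g.attrs["tmin"] = ep.tmin
            g.attrs["channel_labels"] = [s.encode() for s in ep.channel_labels]
            if ep.trial_indices is not None:
                g.create_dataset("trial_indices", data=np.asarray(ep.trial_indices))


def read_dyad_epochs(path: str | Path) -> tuple[EpochSet, EpochSet]:
    out = []
    with h5py.File(path, "r") as f:
        for pid in (1, 2):
            key = f"player{pid}"
            if key not in f:
                raise FormatError(f"epoch file lacks group /{key}")
            g = f[key]
            labels = _labels(g.attrs["channel_labels"])
            trial_indices = g["trial_indices"][()] if "trial_indices" in g else None
            out.append(EpochSet(
                player_id=pid,
                data=g["data"][()],
                sfreq=float(g.attrs["sfreq"]),
                tmin=float(g.attrs["tmin"]),
                channel_labels=labels,
                trial_indices=trial_indices,
            ))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# TFR
# ---------------------------------------------------------------------------

def write_tfr(path: str | Path, tfr: TFRSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=tfr.power.astype(np.float32))
        f.create_dataset("mask", data=tfr.mask)
        f.attrs["freqs"] = tfr.freqs
        f.attrs["times"] = tfr.times
        f.attrs["channel_labels"] = [s.encode() for s in tfr.channel_labels]
        f.attrs["baseline_mode"] = tfr.baseline_mode


def read_tfr(path: str | Path) -> TFRSet:
    with h5py.File(path, "r") as f:
        return TFRSet(
            power=f["power"][()],
            freqs=f.attrs["freqs"],
            times=f.attrs["times"],
            channel_labels=_labels(f.attrs["channel_labels"]),
            baseline_mode=str(f.attrs["baseline_mode"]),
            mask=f["mask"][()],
        )


# ---------------------------------------------------------------------------
# coupling maps
# ---------------------------------------------------------------------------

def write_coupling(path: str | Path, cm: CouplingMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("z", data=cm.z)
        f.create_dataset("rho", data=cm.rho)
        f.attrs["freqs"] = cm.freqs
        f.attrs["times"] = cm.times
        f.attrs["channel_labels"] = [s.encode() for s in cm.channel_labels]
        f.attrs["pair_id"] = cm.pair_id
        f.attrs["condition"] = cm.condition
        f.attrs["n_trials"] = cm.n_trials


def read_coupling(path: str | Path) -> CouplingMap:
    with h5py.File(path, "r") as f:
        pair_id = f.attrs["pair_id"]
        if isinstance(pair_id, (bytes, np.bytes_)):
            pair_id = pair_id.decode()
        elif isinstance(pair_id, np.integer):
            pair_id = int(pair_id)
        return CouplingMap(
            z=f["z"][()],
            rho=f["rho"][()],
            freqs=f.attrs["freqs"],
            times=f.attrs["times"],
            channel_labels=_labels(f.attrs["channel_labels"]),
            pair_id=pair_id,
            condition=str(f.attrs["condition"]),
            n_trials=int(f.attrs["n_trials"]),
        )


# ---------------------------------------------------------------------------
# sensor layout and JSON results
# ---------------------------------------------------------------------------

def write_layout(path: str | Path, layout: SensorLayout) -> None:
    with open(path, "w", encoding="utf-8") as f:
        for label, (x, y, z) in zip(layout.labels, layout.positions):
            f.write(f"{label} {x:.6f} {y:.6f} {z:.6f}\n")


def read_layout(path: str | Path) -> SensorLayout:
    labels, rows = [], []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"layout line must be 'label x y z': {line!r}")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate channel label in layout file")
    pos = np.asarray(rows, dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return SensorLayout(labels=tuple(labels), positions=pos)


def write_json(path: str | Path, obj: dict) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(
        json.dumps(obj, sort_keys=True, indent=2, allow_nan=False) + "\n",
        encoding="utf-8",
    )


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
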