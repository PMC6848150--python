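"""Readers/writers for sessions, ROI sets, sweep sets and result tables.

Imaging sessions are stored as two multi-page TIFF stacks (one per channel)
plus a JSON sidecar holding the per-frame metadata.  ROI sets travel as a
run-length CSV plus a per-cell label CSV (a label-image TIFF reader is also
provided).  Sweep sets are long-format CSV plus a protocol JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from caphys.config import VoltageProtocol
from caphys.imaging.rois import RoiSet
from caphys.synth.ephys import Sweep, SweepSet
from caphys.synth.imaging import ImagingSession


# --- imaging sessions -------------------------------------------------


def write_imaging_session(session: ImagingSession, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "cal.tif", session.cal_stack.astype(np.float32))
    tifffile.imwrite(out / "txred.tif", session.txred_stack.astype(np.float32))
    sidecar = {
        "stim_flags": session.stim_flags.astype(int).tolist(),
        "times_s": session.times_s.tolist(),
        "drug_time_s": session.drug_time_s,
        "condition_label": session.condition_label,
    }
    (out / "session.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return out


def read_imaging_session(in_dir: str | Path) -> ImagingSession:
    d = Path(in_dir)
    meta = json.loads((d / "session.json").read_text())
    return ImagingSession(
        cal_stack=tifffile.imread(d / "cal.tif").astype(np.float64),
        txred_stack=tifffile.imread(d / "txred.tif").astype(np.float64),
        stim_flags=np.asarray(meta["stim_flags"], dtype=bool),
        times_s=np.asarray(meta["times_s"], dtype=float),
        drug_time_s=float(meta["drug_time_s"]),
        condition_label=meta.get("condition_label", ""),
    )


# --- ROI sets ---------------------------------------------------------


def write_rois(rois: RoiSet, out_dir: str | Path, stem: str = "rois") -> Path:
    """Run-length CSV (cell_id,row,col_start,run_length) + per-cell labels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, mask in enumerate(rois.masks):
        for r in range(mask.shape[0]):
            line = mask[r]
            if not line.any():
                continue
            padded = np.concatenate([[False], line, [False]])
            edges = np.flatnonzero(np.diff(padded.astype(int)))
            for start, stop in zip(edges[::2], edges[1::2]):
                rows.append((i, r, int(start), int(stop - start)))
    pd.DataFrame(rows, columns=["cell_id", "row", "col_start", "run_length"]).to_csv(
        out / f"{stem}_rle.csv", index=False
    )
    pd.DataFrame(
        {
            "cell_id": np.arange(rois.n_cells),
            "txred_positive": rois.txred_positive.astype(int),
            "in_focus": rois.in_focus.astype(int),
            "height": rois.masks.shape[1],
            "width": rois.masks.shape[2],
        }
    ).to_csv(out / f"{stem}_cells.csv", index=False)
    return out


def read_rois(in_dir: str | Path, stem: str = "rois") -> RoiSet:
    d = Path(in_dir)
    cells = pd.read_csv(d / f"{stem}_cells.csv")
    rle = pd.read_csv(d / f"{stem}_rle.csv")
    n = len(cells)
    h, w = int(cells["height"].iloc[0]), int(cells["width"].iloc[0])
    masks = np.zeros((n, h, w), dtype=bool)
    for cell_id, row, start, length in rle.itertuples(index=False):
        masks[cell_id, row, start : start + length] = True
    return RoiSet(
        masks=masks,
        txred_positive=cells["txred_positive"].to_numpy(dtype=bool),
        in_focus=cells["in_focus"].to_numpy(dtype=bool),
    )


def read_rois_label_image(tiff_path: str | Path, cells_csv: str | Path) -> RoiSet:
    """Label-image TIFF (0 background, cell i -> i+1) + per-cell label CSV."""
    lab = tifffile.imread(tiff_path)
    cells = pd.read_csv(cells_csv)
    masks = np.stack([lab == i + 1 for i in cells["cell_id"]])
    return RoiSet(
        masks=masks,
        txred_positive=cells["txred_positive"].to_numpy(dtype=bool),
        in_focus=cells["in_focus"].to_numpy(dtype=bool)
        if "in_focus" in cells
        else None,
    )


# --- sweep sets -------------------------------------------------------


def write_sweepset(sweepset: SweepSet, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for k, s in enumerate(sweepset.sweeps):
        _, v = _command(sweepset.protocol, s.level_mv, s.time_ms.size)
        frames.append(
            pd.DataFrame(
                {
                    "sweep_id": f"test_{k:03d}",
                    "time_ms": s.time_ms,
                    "v_mv": v,
                    "current": s.current,
                }
            )
        )
    for k, cur in enumerate(sweepset.pn_sweeps):
        t = np.arange(cur.size) / sweepset.protocol.sampling_khz
        _, v = _command_pn(sweepset.protocol, cur.size)
        frames.append(
            pd.DataFrame(
                {"sweep_id": f"pn_{k:03d}", "time_ms": t, "v_mv": v, "current": cur}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(out / "sweeps.csv", index=False)

    sidecar = {
        "protocol": dataclasses.asdict(sweepset.protocol),
        "sweep_levels_mv": [s.level_mv for s in sweepset.sweeps],
        "sweep_start_times_s": [s.start_time_s for s in sweepset.sweeps],
        "drug_time_s": sweepset.drug_time_s if np.isfinite(sweepset.drug_time_s) else None,
    }
    (out / "protocol.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return out


def _command(protocol: VoltageProtocol, level: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    fs = protocol.sampling_khz
    i_on = int(round(protocol.pre_ms * fs))
    i_off = int(round((protocol.pre_ms + protocol.step_duration_ms) * fs))
    v = np.full(n, protocol.holding_mv)
    v[i_on:i_off] = level
    return np.arange(n) / fs, v


def _command_pn(protocol: VoltageProtocol, n: int) -> tuple[np.ndarray, np.ndarray]:
    fs = protocol.sampling_khz
    i_on = int(round(protocol.pre_ms * fs))
    i_off = int(round((protocol.pre_ms + protocol.step_duration_ms) * fs))
    v = np.full(n, protocol.pn_step_mv[0])
    v[i_on:i_off] = protocol.pn_step_mv[1]
    return np.arange(n) / fs, v


def read_sweepset(in_dir: str | Path) -> SweepSet:
    d = Path(in_dir)
    meta = json.loads((d / "protocol.json").read_text())
    pdict = meta["protocol"]
    protocol = VoltageProtocol.from_dict(pdict)
    table = pd.read_csv(d / "sweeps.csv")
    sweeps: list[Sweep] = []
    pn: list[np.ndarray] = []
    levels = meta["sweep_levels_mv"]
    starts = meta["sweep_start_times_s"]
    test_ids = sorted(i for i in table["sweep_id"].unique() if i.startswith("test_"))
    pn_ids = sorted(i for i in table["sweep_id"].unique() if i.startswith("pn_"))
    for k, sid in enumerate(test_ids):
        sub = table[table["sweep_id"] == sid]
        sweeps.append(
            Sweep(
                time_ms=sub["time_ms"].to_numpy(),
                current=sub["current"].to_numpy(),
                level_mv=float(levels[k]),
                start_time_s=float(starts[k]),
            )
        )
    for sid in pn_ids:
        pn.append(table[table["sweep_id"] == sid]["current"].to_numpy())
    drug = meta.get("drug_time_s")
    return SweepSet(
        sweeps=sweeps,
        protocol=protocol,
        pn_sweeps=pn,
        drug_time_s=float(drug) if drug is not None else np.inf,
    )


# --- misc -------------------------------------------------------------


def config_hash(obj) -> str:
    """Stable short hash of a config (dataclass or plain dict)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
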