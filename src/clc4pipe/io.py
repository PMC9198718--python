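"""File formats: HDF5 cohorts, CSV sweep tables, TIFF image pairs, lane CSVs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .gels import LaneProfile
from .images import ImagePair
from .protocol import ProtocolSpec
from .recording import CohortDataset, GroundTruth, Recording

__all__ = [
    "write_cohort", "read_cohort",
    "read_sweep_table",
    "write_image_pair", "read_image_pair",
    "write_lane", "read_lane",
]


# --------------------------------------------------------------------- HDF5
def write_cohort(cohort: CohortDataset, path, manifest_csv=None) -> None:
    """Write a cohort to HDF5 (groups /cells/<id>, /ground_truth, /manifest).

    Optionally also writes the manifest as a plain CSV next to the HDF5 file.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["protocol"] = json.dumps(
            cohort.recordings[0].protocol.to_dict())
        cells = f.create_group("cells")
        gts = f.create_group("ground_truth")
        for rec in cohort.recordings:
            cid = rec.meta.get("cell_id", f"cell_{id(rec)}")
            g = cells.create_group(cid)
            g.create_dataset("sweeps", data=rec.sweeps, compression="gzip")
            if rec.p8_sweeps is not None:
                g.create_dataset("p8", data=rec.p8_sweeps, compression="gzip")
            g.attrs["fluorescence"] = rec.fluorescence
            g.attrs["meta"] = json.dumps(rec.meta)
            if rec.ground_truth is not None:
                tg = gts.create_group(cid)
                for k, v in rec.ground_truth.__dict__.items():
                    tg.attrs[k] = v
        man = f.create_group("manifest")
        man.attrs["json"] = cohort.manifest.to_json(orient="records")
    if manifest_csv is not None:
        cohort.manifest.to_csv(manifest_csv, index=False)


def read_cohort(path) -> CohortDataset:
    """Read a cohort written by :func:`write_cohort`."""
    with h5py.File(path, "r") as f:
        protocol = ProtocolSpec.from_dict(json.loads(f.attrs["protocol"]))
        recordings = []
        gts = f.get("ground_truth", {})
        for cid in sorted(f["cells"]):
            g = f["cells"][cid]
            gt = None
            if cid in gts:
                gt = GroundTruth(**{k: v for k, v in gts[cid].attrs.items()})
            recordings.append(Recording(
                protocol=protocol,
                sweeps=g["sweeps"][()],
                p8_sweeps=g["p8"][()] if "p8" in g else None,
                fluorescence=float(g.attrs["fluorescence"]),
                meta=json.loads(g.attrs["meta"]),
                ground_truth=gt,
            ))
        from io import StringIO

        manifest = pd.read_json(StringIO(f["manifest"].attrs["json"]),
                                orient="records")
    return CohortDataset(recordings=recordings, manifest=manifest)


# ------------------------------------------------------------ sweep tables
def read_sweep_table(
    path,
    protocol: Optional[ProtocolSpec] = None,
    fluorescence_col: str = "fluorescence",
) -> CohortDataset:
    """Import a tidy CSV sweep table (columns: cell_id, v_mV, t_ms, i_pA).

    For real-data entry: each (cell_id, v_mV) pair holds one sampled trace.
    If ``protocol`` is omitted, a minimal protocol is inferred from the table
    (no pre-segment, no P/8 sweeps; leak subtraction is then unavailable).
    An optional per-cell fluorescence column is carried into the recordings.
    """
    df = pd.read_csv(path)
    required = {"cell_id", "v_mV", "t_ms", "i_pA"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sweep table missing columns: {sorted(missing)}")

    recordings = []
    rows = []
    for cid, sub in df.groupby("cell_id", sort=True):
        volts = np.sort(sub["v_mV"].unique())
        traces = []
        for v in volts:
            tr = sub[sub["v_mV"] == v].sort_values("t_ms")
            traces.append(tr["i_pA"].to_numpy())
        lengths = {len(t) for t in traces}
        if len(lengths) != 1:
            raise ValueError(f"cell {cid}: sweeps have unequal lengths")
        if protocol is None:
            t = np.sort(sub["t_ms"].unique())
            dt = float(np.median(np.diff(t)))
            khz = 1.0 / dt
            n = lengths.pop()
            # assume 1/3 pulse, 2/3 tail when not specified
            n_pulse = n // 3
            protocol_c = ProtocolSpec(
                holding=0.0, v_start=float(volts[0]), v_end=float(volts[-1]),
                v_step=float(volts[1] - volts[0]) if len(volts) > 1 else 10.0,
                pulse_ms=n_pulse * dt, tail_ms=(n - n_pulse) * dt,
                pre_ms=0.0, sample_khz=khz,
            )
        else:
            protocol_c = protocol
        fluor = float(sub[fluorescence_col].iloc[0]) \
            if fluorescence_col in sub.columns else np.nan
        rec = Recording(
            protocol=protocol_c, sweeps=np.vstack(traces), p8_sweeps=None,
            fluorescence=fluor,
            meta={"cell_id": str(cid),
                  "variant": str(sub["variant"].iloc[0])
                  if "variant" in sub.columns else "unknown"},
        )
        recordings.append(rec)
        rows.append({"cell_id": str(cid), "variant": rec.meta["variant"],
                     "fluorescence": fluor})
    return CohortDataset(recordings=recordings, manifest=pd.DataFrame(rows))


# ------------------------------------------------------------------- images
def write_image_pair(pair: ImagePair, path) -> None:
    """Write the two channels as a multi-channel TIFF stack."""
    import tifffile

    stack = np.stack([pair.ch1, pair.ch2]).astype(np.float32)
    tifffile.imwrite(path, stack, metadata={"axes": "CYX"})


def read_image_pair(path, channels: tuple[int, int] = (0, 1)) -> ImagePair:
    """Read a two-channel image pair from a multi-channel TIFF."""
    import tifffile

    arr = np.asarray(tifffile.imread(path), float)
    if arr.ndim == 2:
        raise ValueError("TIFF has a single channel; two are required")
    if arr.ndim == 3 and arr.shape[-1] in (2, 3, 4) and arr.shape[0] not in (2, 3, 4):
        arr = np.moveaxis(arr, -1, 0)  # HWC -> CHW
    c1, c2 = channels
    return ImagePair(ch1=arr[c1], ch2=arr[c2], meta={"path": str(path)})


# -------------------------------------------------------------------- lanes
def write_lane(lane: LaneProfile, csv_path, sidecar_json=None) -> None:
    """Write a lane as two-column CSV plus a JSON sidecar for the MW map."""
    pd.DataFrame({"position_mm": lane.position,
                  "intensity": lane.intensity}).to_csv(csv_path, index=False)
    sidecar = Path(sidecar_json) if sidecar_json else \
        Path(csv_path).with_suffix(".json")
    payload = {"migration_a": lane.mw_map[0], "migration_b": lane.mw_map[1]}
    if lane.bands_truth is not None:
        payload["bands_truth"] = [
            {"label": b.label, "mw_kda": b.mw_kda, "area": b.area,
             "width": b.width} for b in lane.bands_truth]
    sidecar.write_text(json.dumps(payload, indent=1))


def read_lane(csv_path, sidecar_json=None) -> LaneProfile:
    """Read a lane CSV and its JSON MW-map sidecar."""
    from .gels import GelBand

    df = pd.read_csv(csv_path)
    sidecar = Path(sidecar_json) if sidecar_json else \
        Path(csv_path).with_suffix(".json")
    payload = json.loads(sidecar.read_text())
    bands = None
    if "bands_truth" in payload:
        bands = tuple(GelBand(**b) for b in payload["bands_truth"])
    return LaneProfile(
        position=df["position_mm"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        mw_map=(payload["migration_a"], payload["migration_b"]),
        bands_truth=bands,
    )
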