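"""Reading and writing the package's plain-text and TIFF dialects.

Sweeps travel as long-format delimited text (sweep_id, time_s, current_pA)
with a sidecar JSON protocol; image stacks as multi-page TIFF with a
sidecar JSON carrying pixel size, frame interval and scan mode.  No
proprietary acquisition formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calcium import TwoChannelStack
from .ephys import StepProtocol, SweepSet
from .motility import ImageStack


# --- sweeps ------------------------------------------------------------------

def write_sweepset(sweeps: SweepSet, tsv_path: str | Path) -> None:
    """Write sweeps as long-format TSV plus a ``.protocol.json`` sidecar."""
    tsv_path = Path(tsv_path)
    n_sweeps, n = sweeps.sweeps.shape
    df = pd.DataFrame({
        "sweep_id": np.repeat(np.arange(n_sweeps), n),
        "time_s": np.tile(sweeps.time, n_sweeps),
        "current_pA": sweeps.sweeps.ravel(),
    })
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    p = sweeps.protocol
    meta = {
        "sampling_rate_hz": sweeps.sampling_rate,
        "holding_mV": p.holding_mV,
        "step_mV": list(np.atleast_1d(p.step_mV).astype(float)),
        "t_on_s": p.t_on,
        "t_off_s": p.t_off,
        "filter_applied_hz": sweeps.filter_applied,
    }
    sidecar_path(tsv_path, "protocol").write_text(json.dumps(meta, indent=2))


def read_sweepset(tsv_path: str | Path) -> SweepSet:
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t")
    meta = json.loads(sidecar_path(tsv_path, "protocol").read_text())
    sweep_ids = df["sweep_id"].unique()
    n = (df["sweep_id"] == sweep_ids[0]).sum()
    time = df.loc[df["sweep_id"] == sweep_ids[0], "time_s"].to_numpy()
    currents = df["current_pA"].to_numpy().reshape(len(sweep_ids), n)
    step = meta["step_mV"]
    step = step[0] if len(step) == 1 else tuple(step)
    protocol = StepProtocol(holding_mV=meta["holding_mV"], step_mV=step,
                            t_on=meta["t_on_s"], t_off=meta["t_off_s"])
    return SweepSet(time=time, sweeps=currents,
                    sampling_rate=meta["sampling_rate_hz"], protocol=protocol,
                    filter_applied=meta.get("filter_applied_hz"))


def sidecar_path(path: Path, tag: str) -> Path:
    return path.with_suffix(f".{tag}.json")


# --- image stacks ------------------------------------------------------------

def write_image_stack(stack: ImageStack, tif_path: str | Path) -> None:
    tif_path = Path(tif_path)
    tifffile.imwrite(tif_path, stack.frames.astype(np.float32))
    meta = {"frame_interval_s": stack.frame_interval_s,
            "pixel_size_um": stack.pixel_size_um}
    sidecar_path(tif_path, "meta").write_text(json.dumps(meta, indent=2))


def read_image_stack(tif_path: str | Path) -> ImageStack:
    tif_path = Path(tif_path)
    frames = tifffile.imread(tif_path)
    meta = json.loads(sidecar_path(tif_path, "meta").read_text())
    return ImageStack(frames=np.asarray(frames, dtype=float),
                      frame_interval_s=meta["frame_interval_s"],
                      pixel_size_um=meta["pixel_size_um"])


def write_two_channel_stack(stack: TwoChannelStack, tif_path: str | Path) -> None:
    """Interleaved two-channel TIFF (green, red, green, red, ...)."""
    tif_path = Path(tif_path)
    n = stack.green.shape[0]
    inter = np.empty((2 * n,) + stack.green.shape[1:], dtype=np.float32)
    inter[0::2] = stack.green
    inter[1::2] = stack.red
    tifffile.imwrite(tif_path, inter)
    meta = {"pixel_size_um": stack.pixel_size_um,
            "frame_interval_s": stack.frame_interval_s,
            "bit_depth": stack.bit_depth, "scan_mode": stack.scan_mode,
            "channels": ["green", "red"]}
    sidecar_path(tif_path, "meta").write_text(json.dumps(meta, indent=2))


def read_two_channel_stack(tif_path: str | Path) -> TwoChannelStack:
    tif_path = Path(tif_path)
    inter = np.asarray(tifffile.imread(tif_path), dtype=float)
    meta = json.loads(sidecar_path(tif_path, "meta").read_text())
    return TwoChannelStack(green=inter[0::2], red=inter[1::2],
                           pixel_size_um=meta["pixel_size_um"],
                           frame_interval_s=meta["frame_interval_s"],
                           bit_depth=meta["bit_depth"],
                           scan_mode=meta["scan_mode"])


# --- misc --------------------------------------------------------------------

def write_truth(truth: dict, path: str | Path) -> None:
    """JSON truth record; numpy values are converted to plain Python."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(truth, indent=2, default=default))
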