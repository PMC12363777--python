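"""Writers and rendering: metrics CSV, run-summary JSON, HDF5 lattice dumps
and PNG snapshots in the standard tissue palette."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .metrics import counts_frame, thickness_series
from .potts import LatticeState
from .types import (
    BASAL, DAMG, LIMB, MEDIUM, MEMB, N_TYPES, STEM, STROMA, SUPER, TEAR,
    TYPE_NAMES, WALL, WING,
)

__all__ = ["PALETTE", "render_snapshot", "write_metrics_csv",
           "write_events_csv", "write_summary_json", "write_hdf5"]

#: rendering palette (RGB) following the standard tissue legend:
#: stroma lilac-purple, limbal membrane pink, central membrane magenta,
#: stem rose-red, basal peach-orange, wing blue, superficial cyan,
#: tear bright green, air black.
PALETTE: dict[int, tuple[int, int, int]] = {
    MEDIUM: (0, 0, 0),
    TEAR: (0, 230, 60),
    STEM: (220, 60, 90),
    BASAL: (250, 180, 110),
    WING: (60, 90, 230),
    SUPER: (90, 220, 230),
    LIMB: (250, 160, 200),
    MEMB: (230, 40, 160),
    STROMA: (180, 150, 220),
    WALL: (90, 90, 90),
    DAMG: (120, 60, 40),
}


def render_snapshot(state: LatticeState, palette: dict | None = None,
                    scale: int = 1) -> Image.Image:
    """Render the lattice as a PNG-ready image, one pixel per voxel (times
    ``scale``), outer surface up.  Deterministic for a fixed state/palette."""
    palette = palette or PALETTE
    lut = np.zeros((N_TYPES, 3), dtype=np.uint8)
    for t, rgb in palette.items():
        lut[t] = rgb
    rgb = lut[state.type_grid()]
    rgb = rgb[::-1]  # y increases toward the tear film; render it on top
    img = Image.fromarray(rgb, mode="RGB")
    if scale != 1:
        img = img.resize((img.width * scale, img.height * scale),
                         Image.NEAREST)
    return img


def write_metrics_csv(result, path) -> Path:
    """RFC-4180 CSV of per-sample counts and thickness, embedding seed and
    config hash in a comment-free sidecar column set."""
    df = counts_frame(result).copy()
    df["thickness_um"] = thickness_series(result).to_numpy()
    df["day"] = df.index.to_numpy() / result.day_to_mcs
    df["seed"] = result.seed
    df["config_hash"] = result.config.config_hash()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format="%.6g", lineterminator="\n")
    return path


def write_events_csv(result, path) -> Path:
    rows = []
    for mcs, kind, ev in result.events:
        if kind == "mitosis":
            parent, da, db = ev
            rows.append({"mcs": mcs, "event": "mitosis", "cell": parent,
                         "extra": f"{da}|{db}"})
        elif kind == "diff":
            cid, old, new = ev
            rows.append({"mcs": mcs, "event": "differentiation", "cell": cid,
                         "extra": f"{TYPE_NAMES[old]}->{TYPE_NAMES[new]}"})
        else:
            rows.append({"mcs": mcs, "event": "slough", "cell": ev,
                         "extra": ""})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["mcs", "event", "cell", "extra"]).to_csv(
        path, index=False, lineterminator="\n")
    return path


def write_summary_json(result, path, extra: dict | None = None) -> Path:
    from . import metrics as m
    summary = {
        "seed": result.seed,
        "config_hash": result.config.config_hash(),
        "mcs": int(result.state.mcs_counter),
        "stability_day": m.stability_time(result),
        "final_thickness_um": m.thickness_com(result.state),
        "final_counts": result.samples[-1].counts(),
        "injuries": [
            {"mcs": mcs, "classification": rep.classification,
             "deepest_layer_hit": rep.deepest_layer_hit,
             "killed_by_type": rep.killed_by_type,
             "membrane_pixels_destroyed": rep.membrane_pixels_destroyed}
            for mcs, rep in result.injury_reports],
    }
    if extra:
        summary.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(summary, indent=2, default=_json_default)
                    + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


def write_hdf5(result, path) -> Path:
    """Lattice snapshots + per-cell table + field arrays, one group per
    saved MCS."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = result.seed
        f.attrs["config_hash"] = result.config.config_hash()
        st = result.state
        g = f.create_group("final")
        g.create_dataset("owner_grid", data=st.owner_grid,
                         compression="gzip")
        g.create_dataset("ctype", data=st.table.ctype[: st.table.next_id])
        g.create_dataset("volume", data=st.table.volume[: st.table.next_id])
        g.create_dataset("alive",
                         data=st.table.alive[: st.table.next_id])
        if result.sim is not None and result.sim.egf is not None:
            g.create_dataset("egf", data=result.sim.egf.conc,
                             compression="gzip")
        for mcs, grid, ctype in result.snapshots:
            g = f.create_group(f"mcs_{mcs:07d}")
            g.create_dataset("owner_grid", data=grid, compression="gzip")
            g.create_dataset("ctype", data=ctype)
    return path
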