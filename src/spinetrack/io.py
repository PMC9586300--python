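"""File I/O: TIFF stacks with voxel-geometry metadata, CSV tables, manifests.

All tabular coordinates are micrometres; session days are validated against
the run calendar on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detection import SpineObservation
from .synthetic import ImageStack, SpineTimeline

SPINE_TABLE_COLUMNS = [
    "dendrite_id",
    "session_day",
    "x_um",
    "y_um",
    "z_um",
    "length_um",
]


class MalformedTableError(ValueError):
    pass


# ---------------------------------------------------------------------------
# image stacks


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Multi-page TIFF; voxel geometry and jitter in the image description."""
    meta = {
        "pixel_size_xy_um": stack.pixel_size_xy_um,
        "z_step_um": stack.z_step_um,
        "session_day": stack.session_day,
        "jitter_offset_um": list(stack.jitter_offset_um),
    }
    tifffile.imwrite(
        str(path), stack.voxels.astype(np.float32), description=json.dumps(meta)
    )


def read_stack(path: str | Path) -> ImageStack:
    with tifffile.TiffFile(str(path)) as tf:
        vox = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    return ImageStack(
        voxels=vox,
        pixel_size_xy_um=float(meta["pixel_size_xy_um"]),
        z_step_um=float(meta["z_step_um"]),
        session_day=int(meta["session_day"]),
        jitter_offset_um=tuple(meta["jitter_offset_um"]),
    )


# ---------------------------------------------------------------------------
# spine observation tables


def observations_to_frame(obs: list[SpineObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dendrite_id": o.dendrite_id,
                "session_day": o.session_day,
                "x_um": o.position[0],
                "y_um": o.position[1],
                "z_um": o.position[2],
                "length_um": o.length_um,
            }
            for o in obs
        ],
        columns=SPINE_TABLE_COLUMNS,
    )


def write_spine_table(path: str | Path, df: pd.DataFrame) -> None:
    missing = [c for c in SPINE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedTableError(f"missing columns: {missing}")
    df.to_csv(path, index=False, float_format="%.6f")


def read_spine_table(
    path: str | Path, session_days: list[int] | None = None
) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SPINE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedTableError(f"{path}: missing columns: {missing}")
    bad_lines: list[int] = []
    for col in ("session_day", "x_um", "y_um", "z_um", "length_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend(df.index[vals.isna()].tolist())
        df[col] = vals
    if bad_lines:
        # +2: header line plus 1-based numbering
        lines = sorted({i + 2 for i in bad_lines})
        raise MalformedTableError(f"{path}: malformed rows at lines {lines}")
    df["session_day"] = df["session_day"].astype(int)
    if session_days is not None:
        unknown = sorted(set(df["session_day"]) - set(session_days))
        if unknown:
            raise MalformedTableError(
                f"{path}: session days {unknown} not in calendar {session_days}"
            )
    return df


# ---------------------------------------------------------------------------
# ground-truth timelines


def timelines_to_frame(timelines: list[SpineTimeline]) -> pd.DataFrame:
    rows = []
    for tl in timelines:
        for day, alive in zip(tl.session_days, tl.presence):
            rows.append(
                {
                    "spine_id": tl.spine_id,
                    "dendrite_id": tl.dendrite_id,
                    "mouse_id": tl.mouse_id,
                    "group": tl.group,
                    "session_day": day,
                    "x_um": tl.position[0],
                    "y_um": tl.position[1],
                    "z_um": tl.position[2],
                    "length_um": tl.length_um,
                    "alive": int(alive),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# manifests


def write_manifest(
    path: str | Path, stage: str, config_hash: str, seed: int, outputs: list[str]
) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "stage": stage,
                "config_hash": config_hash,
                "seed": seed,
                "outputs": sorted(outputs),
            },
            indent=2,
        )
    )


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
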