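"""Reading and writing the package's tabular formats (CSV) and configs (YAML)."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .synth import ConjunctionObject, ForagerParams, Patch, PatchConfig

PATCH_COLUMNS = [
    "trial_id", "object_id", "cx", "cy", "orientation_deg",
    "role", "disc_color", "rect_color", "grid_col", "grid_row",
]


def write_patches(patches: dict, path) -> None:
    """Write {(participant_id, trial_id): Patch} to one long CSV."""
    frames = []
    for (pid, _trial), patch in sorted(patches.items()):
        df = patch.to_frame()
        df.insert(0, "participant_id", pid)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_patches(path, config: PatchConfig | None = None) -> dict:
    """Inverse of :func:`write_patches`."""
    df = pd.read_csv(path)
    config = config or PatchConfig()
    patches: dict = {}
    for (pid, trial), grp in df.groupby(["participant_id", "trial_id"]):
        objects, cells = [], []
        for row in grp.sort_values("object_id").itertuples(index=False):
            objects.append(
                ConjunctionObject(
                    object_id=int(row.object_id), center_px=(row.cx, row.cy),
                    orientation_deg=int(row.orientation_deg), role=row.role,
                    disc_color=row.disc_color, rect_color=row.rect_color,
                )
            )
            cells.append((int(row.grid_col), int(row.grid_row)))
        patches[(int(pid), int(trial))] = Patch(
            trial_id=int(trial), objects=objects, grid_cells=cells, config=config
        )
    return patches


def write_taplog(taplog: pd.DataFrame, path) -> None:
    taplog.to_csv(path, index=False)


def read_taplog(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_forager_params(path) -> ForagerParams:
    with open(path) as fh:
        return ForagerParams(**yaml.safe_load(fh))


def dump_forager_params(params: ForagerParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh)


def load_patch_config(path) -> PatchConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("grid_extent_px", "screen_px"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PatchConfig(**raw)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
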