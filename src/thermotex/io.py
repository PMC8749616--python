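"""Readers/writers for frames, masks, tables and configuration.

Conventions: images are 8-bit RGB PNG (TIFF also accepted), masks are
single-channel 0/255 PNG, tables are UTF-8 comma-separated CSV with "."
decimals and floats at 9 significant digits, configuration is YAML.
Every written CSV starts with a ``#`` comment line embedding the seed
and a config hash; readers skip comment lines, so write → read → write
is byte-stable.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .synthetic import ThermalFrame

__all__ = [
    "read_frame",
    "write_frame",
    "write_plane",
    "read_table",
    "write_table",
    "write_stage_counts",
    "config_hash",
    "load_config",
    "dump_config",
]


def config_hash(config: dict) -> str:
    """Short deterministic hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _meta_line(seed: int | None, cfg_hash: str | None) -> str:
    return f"# thermotex seed={seed if seed is not None else 'NA'} config={cfg_hash or 'NA'}\n"


def write_table(
    table: pd.DataFrame, path, seed: int | None = None, cfg_hash: str | None = None
) -> None:
    """CSV with a leading provenance comment and 9-significant-digit floats."""
    buf = _io.StringIO()
    buf.write(_meta_line(seed, cfg_hash))
    table.to_csv(buf, index=False, float_format="%.9g")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_stage_counts(counts, path, seed: int | None = None, cfg_hash: str | None = None) -> None:
    payload = {
        "per_approach": {
            "enumerated": counts.enumerated,
            "after_c1": counts.after_c1,
            "after_c2": counts.after_c2,
            "after_glch_drop": counts.after_glch_drop,
            "final": counts.final,
        },
        "totals": counts.totals(),
        "glch_duplicates_glcm": counts.glch_duplicates_glcm,
        "_meta": {"seed": seed, "config": cfg_hash},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def write_frame(frame: ThermalFrame, image_path, mask_path) -> None:
    """Write a frame as an RGB PNG and its mask as a 0/255 PNG."""
    Image.fromarray(frame.image, mode="RGB").save(image_path)
    Image.fromarray((frame.mask.astype(np.uint8) * 255), mode="L").save(mask_path)


def write_plane(plane: np.ndarray, path) -> None:
    """Write a grayscale component plane as PNG or CSV matrix (by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        Image.fromarray(np.asarray(plane, dtype=np.uint8), mode="L").save(path)
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, np.asarray(plane), fmt="%d", delimiter=",")
    else:
        raise ValueError(f"unsupported plane format {path.suffix!r}")


def read_frame(image_path, mask_path, metadata_row) -> ThermalFrame:
    """Load and validate one frame from disk.

    ``metadata_row`` is a mapping (or Series) with mare_id, group,
    subgroup, month, session.  Shape mismatches, non-8-bit images and
    empty masks raise distinct errors.
    """
    with Image.open(image_path) as img:
        if img.mode != "RGB":
            if img.mode in ("I", "I;16", "I;16B", "F"):
                raise ValueError(f"{image_path}: expected 8-bit RGB, got bit depth mode {img.mode}")
            raise ValueError(f"{image_path}: expected RGB image, got mode {img.mode}")
        image = np.asarray(img, dtype=np.uint8)
    with Image.open(mask_path) as mimg:
        mask = np.asarray(mimg.convert("L")) > 127
    if mask.shape != image.shape[:2]:
        raise ValueError(
            f"{mask_path}: mask shape {mask.shape} does not match image {image.shape[:2]}"
        )
    if not mask.any():
        raise ValueError(f"{mask_path}: ROI mask is empty")
    month = metadata_row["month"]
    month = None if pd.isna(month) else int(month)
    return ThermalFrame(
        image=image,
        mask=mask,
        mare_id=str(metadata_row["mare_id"]),
        group=str(metadata_row["group"]),
        subgroup=str(metadata_row["subgroup"]),
        month=month,
        session=int(metadata_row["session"]),
    )


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
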