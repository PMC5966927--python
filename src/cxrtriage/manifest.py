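"""Manifest and image I/O: CSV case lists, PNG images and masks, JSON reports."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage

REQUIRED_COLUMNS = ("case_id", "path", "label")


class SchemaError(ValueError):
    pass


@dataclass
class CaseRecord:
    case_id: str
    path: Path
    label: int
    mask_path: Path | None = None


def read_manifest(path) -> list[CaseRecord]:
    """Validated case records; the mask column is optional (fallback
    segmentation engages when absent)."""
    df = pd.read_csv(path, dtype={"case_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest is missing required column(s): {', '.join(missing)}")
    base = Path(path).parent
    records = []
    for row in df.itertuples(index=False):
        mask = getattr(row, "mask_path", None)
        mask_path = base / str(mask) if isinstance(mask, str) and mask else None
        records.append(CaseRecord(case_id=str(row.case_id), path=base / str(row.path),
                                  label=int(row.label), mask_path=mask_path))
    return records


def load_image(path) -> np.ndarray:
    """PNG to float [0, 1], scaled by the container's max representable value."""
    arr = np.asarray(PILImage.open(path))
    if arr.ndim == 3:  # collapse any colour/alpha to luminance
        arr = arr[..., :3].mean(axis=2)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype in (np.uint16, np.int32, np.uint32):
        return arr.astype(float) / 65535.0
    out = arr.astype(float)
    return np.clip(out, 0.0, 1.0)


def save_image(image: np.ndarray, path) -> None:
    """Write a [0, 1] float image as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    PILImage.fromarray((arr * 255).round().astype(np.uint8)).save(path)


def load_mask(path) -> np.ndarray:
    """Single-channel PNG, any positive pixel counts as foreground."""
    arr = np.asarray(PILImage.open(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)


def save_mask(mask: np.ndarray, path) -> None:
    PILImage.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)


def write_report(report: dict, path) -> None:
    """Pretty-printed JSON with numpy types coerced to plain Python."""
    def _coerce(obj):
        if isinstance(obj, dict):
            return {str(k): _coerce(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_coerce(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return _coerce(obj.tolist())
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj

    Path(path).write_text(json.dumps(_coerce(report), indent=2) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def write_manifest(cases, out_dir: Path, with_masks: bool = True) -> Path:
    """Write phantom cases as PNGs plus a manifest.csv; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        img_name = f"{case.case_id}.png"
        save_image(case.image, out_dir / img_name)
        mask_name = ""
        if with_masks:
            mask_name = f"{case.case_id}_mask.png"
            save_mask(case.mask, out_dir / mask_name)
        rows.append({"case_id": case.case_id, "path": img_name,
                     "mask_path": mask_name, "label": case.label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
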