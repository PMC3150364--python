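"""Reading and writing fields, masks, ground truth and plate maps.

Fields are stored as multi-page TIFF (one page per channel) with the
channel-role mapping carried in the image-description metadata as JSON,
plus an optional ground-truth JSON sidecar.  Plate/condition maps are
YAML or JSON documents keyed by (well, field, frame).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import FieldImage
from .synth import GroundTruth


def write_field_tiff(path: str | Path, fieldimg: FieldImage) -> None:
    """Write one field as a multi-page TIFF, one page per channel role."""
    path = Path(path)
    roles = list(fieldimg.channels)
    desc = json.dumps({"channel_roles": roles,
                       "metadata": _jsonable(fieldimg.metadata)})
    stack = np.stack([fieldimg.channels[r] for r in roles]).astype(np.float32)
    tifffile.imwrite(path, stack, description=desc,
                     photometric="minisblack", planarconfig="separate")


def read_field_tiff(path: str | Path,
                    roles: list[str] | None = None) -> FieldImage:
    """Read a multi-page TIFF back into a FieldImage.

    Channel roles are taken from the embedded description; ``roles``
    overrides the page->role mapping for files written elsewhere.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = {}
        if roles is None:
            desc = tif.pages[0].description
            try:
                payload = json.loads(desc)
                roles = payload["channel_roles"]
                meta = payload.get("metadata", {})
            except (json.JSONDecodeError, KeyError, TypeError):
                raise ValueError(
                    f"{path} carries no channel-role metadata; pass roles=[...]")
    if stack.ndim == 2:
        stack = stack[None]
    if len(roles) != len(stack):
        raise ValueError(f"{path}: {len(stack)} pages but {len(roles)} roles")
    channels = {r: np.clip(np.asarray(p, dtype=float), 0.0, None)
                for r, p in zip(roles, stack)}
    return FieldImage(channels=channels, metadata=meta)


def write_ground_truth(path: str | Path, gt: GroundTruth) -> None:
    Path(path).write_text(gt.to_json())


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def write_label_tiff(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), labels.astype(np.int32))


def write_centroid_csv(path: str | Path, centroids: np.ndarray,
                       strategy: str) -> None:
    lines = ["cell_id,row,col,strategy"]
    for i, (r, c) in enumerate(np.asarray(centroids, dtype=float)):
        lines.append(f"{i},{r:.3f},{c:.3f},{strategy}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# plate map
# --------------------------------------------------------------------------

@dataclass
class PlateMapEntry:
    well: str
    field: int
    frame: int
    file: str
    compound: str = ""
    dose_m: float | None = None
    time_min: float | None = None
    induced: bool = True
    channel_roles: list[str] | None = None

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.well, self.field, self.frame)


@dataclass
class PlateMap:
    """Condition map for acquired images: (well, field, frame) -> entry."""

    entries: list[PlateMapEntry] = field(default_factory=list)

    def __post_init__(self):
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("plate map keys (well, field, frame) must be unique")
        if not self.entries:
            raise ValueError("plate map is empty")

    @classmethod
    def load(cls, path: str | Path) -> "PlateMap":
        path = Path(path)
        text = path.read_text()
        doc = (json.loads(text) if path.suffix.lower() == ".json"
               else yaml.safe_load(text))
        if not isinstance(doc, dict) or "entries" not in doc:
            raise ValueError(f"{path}: plate map must be a mapping with 'entries'")
        entries = [PlateMapEntry(**e) for e in doc["entries"]]
        pm = cls(entries=entries)
        missing = [e.file for e in entries
                   if not (path.parent / e.file).exists()]
        if missing:
            raise FileNotFoundError(
                f"plate map references missing images: {missing[:5]}")
        return pm


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
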