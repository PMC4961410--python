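"""Configuration and on-disk formats.

Interchange formats:

* event tables — CSV (primary) and ARFF (numeric attributes plus one
  nominal class attribute, mirroring the cytometry-software-to-R handoff);
* images — one multi-page 16-bit TIFF per tile (one page per channel)
  plus a JSON layout sidecar with per-tile pixel offsets;
* configuration, gating strategies and thresholds — YAML.

Every output carries the configuration hash so a run is traceable to its
parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import CHANNELS, EventTable, LayoutError, ValidationError
from .imaging import ImagePipelineConfig, TileGrid

__all__ = [
    "PipelineConfig",
    "write_events_csv", "read_events_csv",
    "write_events_arff", "read_events_arff",
    "write_tiles", "read_tiles",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (YAML-serializable).

    ``gating_channels`` are thresholded on the representative sample
    (first sample of the batch unless ``representative_sample`` names
    one); ``manual_cutoffs`` override derivation per channel.
    """

    preset: str = "fig2d_capture"
    seed: int = 0
    n_cells: Optional[int] = None
    mode: str = "events"                    # events | images
    # image rendering
    field_shape: tuple[int, int] = (1024, 1024)
    grid_shape: tuple[int, int] = (2, 2)
    overlap_frac: float = 0.10
    background: float = 500.0
    noise_sd: float = 50.0
    touching_rate: float = 0.05
    # image pipeline
    hoechst_threshold: float = 800.0
    min_area: int = 20
    split_min_distance: int = 7
    cytoplasm_dilation: int = 3
    background_method: str = "median"
    # gating
    gating_channels: tuple[str, ...] = ("cd45", "cd11b", "pck", "pdl1")
    manual_cutoffs: dict = field(default_factory=dict)
    representative_sample: Optional[str] = None
    rederive_per_sample: bool = False       # never the default
    id_marker: Optional[str] = None         # None: take from scenario
    out_dir: str = "out"

    def __post_init__(self) -> None:
        if self.mode not in ("events", "images"):
            raise ValidationError(f"mode must be events/images: {self.mode}")
        if not (0 <= self.overlap_frac < 1):
            raise ValidationError("overlap_frac must be in [0, 1)")
        if self.noise_sd < 0 or self.background < 0:
            raise ValidationError("noise_sd and background must be >= 0")
        self.field_shape = tuple(int(v) for v in self.field_shape)  # type: ignore
        self.grid_shape = tuple(int(v) for v in self.grid_shape)    # type: ignore
        self.gating_channels = tuple(self.gating_channels)          # type: ignore

    def image_pipeline_config(self) -> ImagePipelineConfig:
        return ImagePipelineConfig(
            hoechst_threshold=self.hoechst_threshold,
            min_area=self.min_area,
            split_min_distance=self.split_min_distance,
            cytoplasm_dilation=self.cytoplasm_dilation,
            background_method=self.background_method,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: Path | str) -> None:
        d = asdict(self)
        d["field_shape"] = list(self.field_shape)
        d["grid_shape"] = list(self.grid_shape)
        d["gating_channels"] = list(self.gating_channels)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        d = yaml.safe_load(path.read_text()) or {}
        return cls(**d)


# ---------------------------------------------------------------------------
# event tables: CSV and ARFF
# ---------------------------------------------------------------------------

_META_COLS = ("sample_id", "capture_antibody")


def write_events_csv(events: EventTable, path: Path | str) -> None:
    df = events.data.copy()
    df.insert(0, "sample_id", events.sample_id)
    df.insert(1, "capture_antibody", events.capture_antibody)
    header_meta = {k: v for k, v in events.provenance.items()
                   if isinstance(v, (str, int, float))}
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# ctcgate events {json.dumps(header_meta, sort_keys=True)}\n")
        df.to_csv(fh, index=False)


def read_events_csv(path: Path | str) -> EventTable:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        prov = {}
        if first.startswith("# ctcgate events"):
            try:
                prov = json.loads(first.split("events", 1)[1])
            except json.JSONDecodeError:
                prov = {}
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    sample_id = str(df["sample_id"].iloc[0]) if len(df) else "sample"
    antibody = str(df["capture_antibody"].iloc[0]) if len(df) else "EpCAM"
    channels = tuple(c for c in CHANNELS if c in df.columns)
    df = df.drop(columns=[c for c in _META_COLS if c in df.columns])
    return EventTable(sample_id=sample_id, capture_antibody=antibody,
                      data=df, channel_names=channels, provenance=prov)


def write_events_arff(events: EventTable, path: Path | str,
                      class_col: Optional[str] = None) -> None:
    """Minimal ARFF writer: numeric attributes plus one nominal class.

    ``class_col`` defaults to the strict label column when present, else
    the truth class, else no nominal attribute.
    """
    df = events.data
    if class_col is None:
        class_col = next((c for c in ("label_strict", "label", "truth_class")
                          if c in df.columns), None)
    numeric = [c for c in df.columns
               if c != class_col and pd.api.types.is_numeric_dtype(df[c])]
    lines = [f"@RELATION ctcgate_{events.sample_id}", ""]
    for c in numeric:
        lines.append(f"@ATTRIBUTE {c} NUMERIC")
    if class_col is not None:
        levels = sorted(str(v) for v in df[class_col].dropna().unique())
        lines.append(f"@ATTRIBUTE {class_col} {{{','.join(levels)}}}")
    lines.extend(["", "@DATA"])
    for _, row in df.iterrows():
        vals = [repr(float(row[c])) for c in numeric]
        if class_col is not None:
            v = row[class_col]
            vals.append("?" if pd.isna(v) else str(v))
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_events_arff(path: Path | str) -> pd.DataFrame:
    """Read back an ARFF file written by :func:`write_events_arff`."""
    names: list[str] = []
    nominal: dict[str, bool] = {}
    rows: list[list] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        upper = line.upper()
        if upper.startswith("@RELATION"):
            continue
        if upper.startswith("@ATTRIBUTE"):
            _, name, spec = line.split(None, 2)
            names.append(name)
            nominal[name] = spec.strip().startswith("{")
            continue
        if upper.startswith("@DATA"):
            in_data = True
            continue
        if in_data:
            parts = line.split(",")
            if len(parts) != len(names):
                raise ValidationError(f"ARFF row has {len(parts)} values, "
                                      f"expected {len(names)}")
            row = [p if nominal[n] else float(p)
                   for p, n in zip(parts, names)]
            row = [None if v == "?" else v for v in row]
            rows.append(row)
    return pd.DataFrame(rows, columns=names)


# ---------------------------------------------------------------------------
# tiled images: multi-page TIFF + JSON layout sidecar
# ---------------------------------------------------------------------------

def write_tiles(grid: TileGrid, out_dir: Path | str, stem: str = "tile") -> Path:
    """Write one 16-bit multi-page TIFF per tile plus ``layout.json``.

    Returns the sidecar path. Page k of each TIFF is channel k in
    ``channel_names`` order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for k, (tile, off) in enumerate(zip(grid.tiles, grid.offsets)):
        fname = f"{stem}_{k:03d}.tif"
        tifffile.imwrite(out_dir / fname, tile.astype(np.uint16))
        files.append({"file": fname, "row_offset": int(off[0]),
                      "col_offset": int(off[1])})
    sidecar = {
        "channel_names": list(grid.channel_names),
        "bit_depth": grid.bit_depth,
        "tiles": files,
        "meta": {k: v for k, v in grid.meta.items()
                 if isinstance(v, (str, int, float, list, tuple))},
    }
    sidecar_path = out_dir / "layout.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, default=list))
    return sidecar_path


def read_tiles(layout_path: Path | str) -> TileGrid:
    layout_path = Path(layout_path)
    if not layout_path.exists():
        raise LayoutError(f"layout sidecar not found: {layout_path}")
    sidecar = json.loads(layout_path.read_text())
    tiles, offsets = [], []
    for entry in sidecar["tiles"]:
        if "row_offset" not in entry or "col_offset" not in entry:
            raise LayoutError(f"tile entry missing offsets: {entry}")
        arr = tifffile.imread(layout_path.parent / entry["file"])
        if arr.ndim == 2:
            arr = arr[None]
        tiles.append(arr)
        offsets.append((int(entry["row_offset"]), int(entry["col_offset"])))
    meta = sidecar.get("meta", {})
    return TileGrid(tiles=tiles, offsets=offsets,
                    channel_names=tuple(sidecar["channel_names"]),
                    bit_depth=sidecar.get("bit_depth", 16), meta=meta)
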