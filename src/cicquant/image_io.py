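"""Reading and writing images, label masks, ground truth, and results tables.

Images travel as multi-page TIFF with channel identity supplied by the
caller (a ``channel_map``), never inferred from TIFF tags.  Ground truth is
JSON, results are CSV.  All writers are deterministic: identical inputs give
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

#: Channel sets accepted by :func:`read_image`.  Fluorescence mode carries the
#: viable (green), dead (red) and nuclear (DAPI) channels; tissue mode a
#: single immunohistochemistry channel.
FLUORESCENCE_CHANNELS = frozenset({"green", "red", "dapi"})
TISSUE_CHANNELS = frozenset({"ihc"})

#: Column order of the per-sample results table written by
#: :func:`write_results`.
RESULTS_COLUMNS = [
    "sample_id",
    "mode",
    "n_viable",
    "n_dead",
    "n_cic",
    "cic_rate_percent",
    "area_mm2",
    "cic_per_mm2",
    "ecad_mean_gray",
    "ecad_score",
    "t_stage",
    "n_stage",
    "m_stage",
]


@dataclass
class ImageStack:
    """Named 2-D channels plus the physical pixel size.

    Parameters
    ----------
    channels
        Mapping from channel name (``green``/``red``/``dapi`` or ``ihc``)
        to a 2-D intensity array.  All channels must share one shape.
    pixel_size_um
        Micrometers per pixel, > 0.
    bit_depth
        8 or 16; intensities must fit.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree on shape: {sorted(shapes)}")
        limit = 2**self.bit_depth - 1
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if ch.max(initial=0) > limit:
                raise ValueError(
                    f"channel {name!r} exceeds {self.bit_depth}-bit range"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def _validate_channel_names(names: set[str]) -> None:
    if names != set(FLUORESCENCE_CHANNELS) and names != set(TISSUE_CHANNELS):
        raise ValueError(
            f"channel_map names {sorted(names)} match neither fluorescence mode "
            f"{sorted(FLUORESCENCE_CHANNELS)} nor tissue mode {sorted(TISSUE_CHANNELS)}"
        )


def write_image(path: str | Path, stack: ImageStack, channel_map: Mapping[str, int]) -> None:
    """Write an :class:`ImageStack` as a multi-page TIFF.

    ``channel_map`` gives the page index for each channel name; the same map
    must be used to read the file back.
    """
    _validate_channel_names(set(channel_map))
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    pages = [None] * len(channel_map)
    for name, idx in channel_map.items():
        pages[idx] = stack.channels[name].astype(dtype)
    tifffile.imwrite(str(path), np.stack(pages), photometric="minisblack")


def read_image(path: str | Path, channel_map: Mapping[str, int],
               pixel_size_um: float = 2.0) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Raises ``ValueError`` if the channel_map is incomplete for its mode or
    names a page the file does not have (the error lists available planes).
    """
    _validate_channel_names(set(channel_map))
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    n_pages = data.shape[0]
    for name, idx in channel_map.items():
        if not 0 <= idx < n_pages:
            raise ValueError(
                f"channel {name!r} maps to page {idx} but file has pages 0..{n_pages - 1}"
            )
    bit_depth = 16 if data.dtype.itemsize > 1 else 8
    channels = {name: data[idx] for name, idx in channel_map.items()}
    return ImageStack(channels=channels, pixel_size_um=pixel_size_um, bit_depth=bit_depth)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a labeled mask as a 16-bit TIFF (background 0, labels exact)."""
    mask = np.asarray(mask)
    if mask.max(initial=0) > 65535:
        raise ValueError(f"mask has {int(mask.max())} > 65535 labels; cannot store as 16-bit")
    if mask.min(initial=0) < 0:
        raise ValueError("mask labels must be non-negative")
    tifffile.imwrite(str(path), mask.astype(np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a labeled mask written by :func:`write_mask`."""
    return tifffile.imread(str(path)).astype(np.int32)


def write_results(path: str | Path, table: pd.DataFrame) -> None:
    """Write a per-sample results table as CSV.

    The header is fixed (:data:`RESULTS_COLUMNS`), floats are printed at four
    decimals, and rows are sorted by ``sample_id`` so repeated writes of the
    same table are byte-identical.
    """
    out = table.copy()
    for col in RESULTS_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[RESULTS_COLUMNS].sort_values("sample_id", kind="mergesort")
    out.to_csv(path, index=False, float_format="%.4f", lineterminator="\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV back; integer count columns are restored."""
    df = pd.read_csv(path)
    for col in ("n_viable", "n_dead", "n_cic"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df


def write_ground_truth(path: str | Path, truth) -> None:
    """Serialize a ground-truth record (objects + pairs) to JSON."""
    payload = {
        "objects": [
            {
                "object_id": int(o.object_id),
                "cls": o.cls,
                "center": [float(o.center[0]), float(o.center[1])],
                "radius_px": float(o.radius_px),
            }
            for o in truth.objects
        ],
        "pairs": [[int(h), int(e)] for h, e in truth.pairs],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_ground_truth(path: str | Path):
    """Load ground truth written by :func:`write_ground_truth`."""
    from .synthetic_data import GroundTruth, TruthObject

    payload = json.loads(Path(path).read_text())
    objects = [
        TruthObject(
            object_id=o["object_id"],
            cls=o["cls"],
            center=(o["center"][0], o["center"][1]),
            radius_px=o["radius_px"],
        )
        for o in payload["objects"]
    ]
    pairs = [(h, e) for h, e in payload["pairs"]]
    return GroundTruth(objects=objects, pairs=pairs)


def ground_truth_frame(truth) -> pd.DataFrame:
    """Flat one-row-per-object view of a ground-truth record."""
    return pd.DataFrame(
        [
            {
                "object_id": o.object_id,
                "cls": o.cls,
                "center_row": o.center[0],
                "center_col": o.center[1],
                "radius_px": o.radius_px,
            }
            for o in truth.objects
        ]
    )


@dataclass
class RunConfig:
    """Run-level configuration: paths, channel map, parameters, seed.

    Keys (all optional except ``channel_map`` for image runs):

    - ``image``: path of the input TIFF
    - ``channel_map``: channel name -> page index
    - ``pixel_size_um``: micrometers per pixel
    - ``segmentation``: kwargs for ``SegmentationParams``
    - ``detection``: kwargs for ``CicParams``
    - ``seed``: integer seed for any stochastic step
    """

    image: str | None = None
    channel_map: dict[str, int] = field(default_factory=dict)
    pixel_size_um: float = 2.0
    segmentation: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**raw)


def save_config(path: str | Path, config: RunConfig) -> None:
    payload = {
        "image": config.image,
        "channel_map": dict(config.channel_map),
        "pixel_size_um": config.pixel_size_um,
        "segmentation": dict(config.segmentation),
        "detection": dict(config.detection),
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
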