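"""Image, annotation, configuration and result-table input/output.

Conventions: coordinates are 0-based, row-major ``(row, col)``; rectangles are
half-open.  Multi-channel images are held as a named map of 2-D planes sharing
one pixel size.  Fiber ROI sets are persisted as 16-bit label-mask TIFFs
(0 = background, k = fiber k) plus CSV tables, which together are lossless.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

log = logging.getLogger("myoseg")

#: channel names the pipeline understands
LAMININ = "laminin"
TYPE_CHANNELS = ("type_I", "type_IIa", "type_IIb")
KNOWN_CHANNELS = (LAMININ,) + TYPE_CHANNELS

#: the eight final fiber-type categories (4 pure + 3 mixed + IIx)
FIBER_LABELS = ("I", "IIa", "IIb", "IIx", "I/IIa", "I/IIb", "IIa/IIb", "I/IIa/IIb")

MORPHO_COLUMNS = (
    "area_um2",
    "perimeter_um",
    "circularity",
    "feret_um",
    "min_feret_um",
    "feret_angle_deg",
    "feret_ar",
    "roundness",
    "solidity",
)


class MyosegError(Exception):
    """Base class for all package errors."""


def _check_plane(plane: np.ndarray, bit_depth: int) -> None:
    if plane.ndim != 2:
        raise MyosegError(f"channel planes must be 2-D, got shape {plane.shape}")
    if not np.issubdtype(plane.dtype, np.integer):
        raise MyosegError(f"channel planes must be integer typed, got {plane.dtype}")
    hi = 2**bit_depth - 1
    if plane.size and (plane.min() < 0 or plane.max() > hi):
        raise MyosegError(f"pixel values outside the {bit_depth}-bit range [0, {hi}]")


@dataclass
class MultiChannelImage:
    """Aligned 2-D channel planes plus physical pixel size.

    ``channels`` must contain a ``"laminin"`` plane (the boundary stain) and
    zero or more of ``type_I`` / ``type_IIa`` / ``type_IIb`` (MyHC stains).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise MyosegError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size_um <= 0:
            raise MyosegError("pixel_size_um must be positive")
        if LAMININ not in self.channels:
            raise MyosegError('channels must include a "laminin" plane')
        shapes = set()
        for name, plane in self.channels.items():
            if name not in KNOWN_CHANNELS:
                raise MyosegError(
                    f"unknown channel name {name!r}; expected one of {KNOWN_CHANNELS}"
                )
            _check_plane(plane, self.bit_depth)
            shapes.add(plane.shape)
        if len(shapes) != 1:
            raise MyosegError(f"channel planes differ in shape: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def height_px(self) -> int:
        return self.shape[0]

    @property
    def width_px(self) -> int:
        return self.shape[1]

    @property
    def laminin(self) -> np.ndarray:
        return self.channels[LAMININ]

    @property
    def type_channels(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.channels.items() if k != LAMININ}


@dataclass
class AnnotationMask:
    """Sparse two-class pixel annotations: 0 unlabeled, 1 boundary, 2 intra-fiber."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        bad = np.setdiff1d(np.unique(self.labels), [0, 1, 2])
        if bad.size:
            raise MyosegError(f"annotation labels must be in {{0,1,2}}, found {bad}")

    def require_both_classes(self) -> None:
        if not ((self.labels == 1).any() and (self.labels == 2).any()):
            raise MyosegError(
                "training annotations need at least one boundary (1) and one "
                "intra-fiber (2) pixel"
            )


@dataclass
class GateConfig:
    """Morphometric exclusion gates (closed intervals) and ROI expansion.

    Defaults are the recommended ranges: area 50–6000 µm², circularity 0.3–1.0,
    minimum Feret 5.5–60 µm, Feret aspect ratio 1–4.
    """

    area_um2: tuple[float, float] = (50.0, 6000.0)
    circularity: tuple[float, float] = (0.3, 1.0)
    min_feret_um: tuple[float, float] = (5.5, 60.0)
    feret_ar: tuple[float, float] = (1.0, 4.0)
    roi_expand_px: int = 2
    exclude_edge_fibers: bool = True

    def __post_init__(self) -> None:
        for name in ("area_um2", "circularity", "min_feret_um", "feret_ar"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise MyosegError(f"gate {name}: min {lo} > max {hi}")
        if self.roi_expand_px < 0:
            raise MyosegError("roi_expand_px must be non-negative")


@dataclass
class RunConfig:
    """Structured run configuration housing every adjustable parameter."""

    channel_map: dict[str, int] = field(
        default_factory=lambda: {"type_I": 0, "laminin": 1, "type_IIa": 2, "type_IIb": 3}
    )
    pixel_size_um: float | None = None
    grid_factor: int = 4
    saturated_fraction: float = 0.0035
    gaussian_sigma_post: float = 2.0
    gate: GateConfig = field(default_factory=GateConfig)
    #: per type-channel intensity threshold: a number, or "auto" for Otsu
    thresholds: dict[str, float | str] = field(
        default_factory=lambda: {c: "auto" for c in TYPE_CHANNELS}
    )
    seed: int = 0
    n_trees: int = 200
    output_dir: str = "myoseg_out"

    def __post_init__(self) -> None:
        if not 2 <= self.grid_factor <= 5:
            raise MyosegError(f"grid_factor must be in [2, 5], got {self.grid_factor}")
        for name in self.channel_map:
            if name not in KNOWN_CHANNELS:
                raise MyosegError(f"unknown channel {name!r} in channel_map")
        for name in self.thresholds:
            if name not in TYPE_CHANNELS:
                raise MyosegError(f"threshold given for non-type channel {name!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "gate" in raw:
            g = raw["gate"]
            for k in ("area_um2", "circularity", "min_feret_um", "feret_ar"):
                if k in g:
                    g[k] = tuple(g[k])
            raw["gate"] = GateConfig(**g)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dict(self.__dict__)
        d["gate"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.gate.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(d))


# ---------------------------------------------------------------------------
# image reading / writing


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    """Pixel edge length in µm from TIFF resolution tags, if present."""
    page = tf.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0:
        return None
    unit = tags.get("ResolutionUnit")
    per_unit = num / den  # pixels per unit
    scale = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", 1), None)
    if scale is None:  # unit unspecified: assume µm-denominated resolution
        scale = 1.0
    return scale / per_unit


def read_image(path: str | Path, cfg: RunConfig) -> MultiChannelImage:
    """Read a multi-plane TIFF into a :class:`MultiChannelImage` per ``cfg``."""
    path = Path(path)
    if not path.exists():
        raise MyosegError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta_px = _pixel_size_from_tiff(tf)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] > 8:
        arr = np.moveaxis(arr, -1, 0)  # H,W,C layout
    n_planes = arr.shape[0]
    needed = max(cfg.channel_map.values()) + 1
    if n_planes < needed:
        raise MyosegError(
            f"image has {n_planes} plane(s) but channel_map references plane "
            f"{needed - 1}"
        )
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise MyosegError(f"unsupported TIFF dtype {arr.dtype}; need uint8/uint16")
    px = cfg.pixel_size_um if cfg.pixel_size_um is not None else meta_px
    if px is None:
        warnings.warn(
            "pixel size not in config nor TIFF metadata; defaulting to 1.0 um/px",
            stacklevel=2,
        )
        px = 1.0
    channels = {name: arr[idx] for name, idx in cfg.channel_map.items()}
    return MultiChannelImage(channels=channels, pixel_size_um=px, bit_depth=bit_depth)


def write_image(path: str | Path, img: MultiChannelImage,
                order: Sequence[str] | None = None) -> None:
    """Write channels as a multi-plane TIFF with µm resolution metadata."""
    names = list(order) if order is not None else sorted(img.channels)
    stack = np.stack([img.channels[n] for n in names])
    ppu = 10000.0 / img.pixel_size_um  # pixels per cm
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        resolution=(ppu, ppu),
        resolutionunit="CENTIMETER",
        metadata={"axes": "CYX", "channels": names},
    )


def stack_channels(planes: Sequence[np.ndarray], names: Sequence[str],
                   pixel_size_um: float = 1.0) -> MultiChannelImage:
    """Assemble single-channel planes into one multi-channel image.

    Planes must agree in shape and bit depth; order is preserved via ``names``.
    """
    if len(planes) < 2:
        raise MyosegError("need at least 2 planes to stack")
    if len(names) != len(planes):
        raise MyosegError("one name per plane required")
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise MyosegError(f"plane dimensions differ: {sorted(shapes)}")
    dtypes = {p.dtype for p in planes}
    if len(dtypes) != 1:
        raise MyosegError(f"mixed bit depths: {sorted(str(d) for d in dtypes)}")
    bit_depth = 8 if planes[0].dtype == np.uint8 else 16
    return MultiChannelImage(
        channels=dict(zip(names, planes)),
        pixel_size_um=pixel_size_um,
        bit_depth=bit_depth,
    )


def split_channels(img: MultiChannelImage) -> dict[str, np.ndarray]:
    return dict(img.channels)


# ---------------------------------------------------------------------------
# label masks and tables


def write_label_mask(path: str | Path, records, shape: tuple[int, int],
                     expanded: bool = False) -> np.ndarray:
    """Render fiber ROIs as a 16-bit label mask (0 background, k = fiber k)."""
    mask = np.zeros(shape, dtype=np.uint16)
    for rec in records:
        rows, cols = rec.expanded_pixels if expanded else rec.pixels
        mask[rows, cols] = rec.id
    tifffile.imwrite(path, mask)
    return mask


def _label_slug(label: str) -> str:
    return label.replace("/", "_")


def records_to_frame(records, calls=None) -> pd.DataFrame:
    """Flatten fiber records (and optional type calls) to a tidy table."""
    rows = []
    if not records:
        cols = ["id"] + (["type"] if calls is not None else []) + list(MORPHO_COLUMNS)
        cols += ["centroid_row", "centroid_col", "morphometrics_post_expansion"]
        return pd.DataFrame(columns=cols)
    for rec in records:
        row = {"id": rec.id}
        if calls is not None:
            if rec.id not in calls.labels:
                raise MyosegError(f"fiber {rec.id} has no final type call")
            row["type"] = calls.labels[rec.id]
            for ch, member in calls.memberships[rec.id].items():
                row[f"pos_{ch}"] = member
        for col in MORPHO_COLUMNS:
            row[col] = getattr(rec, col)
        row["centroid_row"], row["centroid_col"] = rec.centroid
        row["morphometrics_post_expansion"] = rec.measured_post_expansion
        for ch, st in sorted(rec.channel_stats.items()):
            for stat in ("mean", "sd", "min", "max", "mode"):
                row[f"{ch}_{stat}"] = st[stat]
        rows.append(row)
    return pd.DataFrame(rows)


def write_fiber_tables(records, calls, outdir: str | Path) -> dict[str, Path]:
    """Write the all-fibers table plus one CSV per final type category.

    The per-category row counts partition the all-fibers table exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = records_to_frame(records, calls)
    paths = {"all": outdir / "fibers_all.csv"}
    frame.to_csv(paths["all"], index=False)
    for label in FIBER_LABELS:
        sub = frame[frame["type"] == label] if len(frame) else frame
        p = outdir / f"fibers_{_label_slug(label)}.csv"
        if len(frame):
            sub.to_csv(p, index=False)
        else:  # header-only tables for an empty run
            frame.to_csv(p, index=False)
        paths[label] = p
    return paths
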