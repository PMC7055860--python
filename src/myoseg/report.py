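"""Run summaries, CSA section maps, histogram binning and stain quality.

"Total section size" is the area of the tissue mask derived from the laminin
channel (Gaussian blur sigma 5 px, Otsu threshold, fill holes, keep the
largest component), reported in mm²; the sum of fiber CSAs is reported
alongside for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib import colormaps
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import FIBER_LABELS, MultiChannelImage, MyosegError

#: boundary:intra-fiber intensity ratio above which a stain counts as good
STAIN_QUALITY_CUTOFF = 5.0


def fd_bin_width(values) -> float:
    """Freedman–Diaconis histogram bin width, ``2 * IQR * n**(-1/3)``.

    IQR uses linearly interpolated quantiles.  When the IQR is zero the full
    range over sqrt(n) is used instead (with a warning); a constant sample
    falls back to a width of 1.
    """
    v = np.asarray(list(values), dtype=np.float64)
    n = v.size
    if n < 2:
        raise MyosegError("need at least 2 values for a bin width")
    q75, q25 = np.percentile(v, [75, 25])  # linear interpolation
    iqr = q75 - q25
    if iqr > 0:
        return 2.0 * iqr / n ** (1.0 / 3.0)
    warnings.warn("IQR is zero; falling back to range/sqrt(n) bin width",
                  stacklevel=2)
    rng = np.ptp(v)
    return rng / np.sqrt(n) if rng > 0 else 1.0


# ---------------------------------------------------------------------------
# stain quality


def stain_quality(img: MultiChannelImage, boundary_mask: np.ndarray,
                  grid: int = 3, min_pixels: int = 32) -> tuple[float, str]:
    """Boundary:intra-fiber laminin intensity ratio and its quality label.

    The image is split into a ``grid``×``grid`` panel of locations; in each
    location holding enough pixels of both classes the ratio of median laminin
    intensity on boundary versus intra-fiber pixels is taken, and the overall
    ratio is the median over locations (medians are robust to hot pixels and
    staining non-uniformity).  Ratio > 5 is "good", ≤ 5 is "poor"; the label
    is decided on the ratio rounded to 2 decimals (the reported precision).
    """
    lam = img.laminin
    if boundary_mask.shape != lam.shape:
        raise MyosegError("boundary mask shape does not match the image")
    inside = boundary_mask.astype(bool)
    # the intra-fiber space lies within the tissue: exclude the empty
    # background around the section from the comparison
    try:
        # erode so the blurred-threshold mask cannot overhang the section
        # edge and leak dark background into the intra-fiber sample
        tissue = ndimage.binary_erosion(tissue_mask(lam), iterations=8)
        if not (tissue & ~inside).any():
            tissue = np.ones_like(inside)
    except MyosegError:
        tissue = np.ones_like(inside)
    inside &= tissue
    outside = ~boundary_mask.astype(bool) & tissue
    if not inside.any() or not outside.any():
        raise MyosegError("degenerate boundary mask: need both classes")
    h, w = lam.shape
    ratios = []
    re = np.linspace(0, h, grid + 1).astype(int)
    ce = np.linspace(0, w, grid + 1).astype(int)
    for i in range(grid):
        for j in range(grid):
            sl = (slice(re[i], re[i + 1]), slice(ce[j], ce[j + 1]))
            b = lam[sl][inside[sl]]
            f = lam[sl][outside[sl]]
            if b.size < min_pixels or f.size < min_pixels:
                continue
            med_f = np.median(f)
            if med_f > 0:
                ratios.append(float(np.median(b)) / float(med_f))
    if not ratios:
        # fall back to a single global measurement
        med_f = float(np.median(lam[outside]))
        if med_f <= 0:
            raise MyosegError("intra-fiber median intensity is zero")
        ratios = [float(np.median(lam[inside])) / med_f]
    ratio = float(np.median(ratios))
    label = "good" if round(ratio, 2) > STAIN_QUALITY_CUTOFF else "poor"
    return ratio, label


def tissue_mask(laminin: np.ndarray, sigma: float = 5.0) -> np.ndarray:
    """Whole-section tissue mask from the laminin channel."""
    x = ndimage.gaussian_filter(laminin.astype(np.float64), sigma)
    if np.ptp(x) == 0:
        raise MyosegError("constant laminin channel: no tissue detectable")
    mask = x > threshold_otsu(x)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    largest = 1 + np.argmax(ndimage.sum_labels(mask, labels, range(1, n + 1)))
    return labels == largest


# ---------------------------------------------------------------------------
# CSA map


def csa_map(records, shape: tuple[int, int], cmap: str = "viridis",
            expanded: bool = False) -> tuple[np.ndarray, tuple[float, float]]:
    """Color-coded section map: each fiber painted by a monotone scale of CSA.

    Returns an RGB uint8 image (black background) and the (vmin, vmax) CSA
    range of the scale.
    """
    rgb = np.zeros(shape + (3,), dtype=np.uint8)
    if not records:
        return rgb, (0.0, 0.0)
    areas = np.array([rec.area_um2 for rec in records])
    vmin, vmax = float(areas.min()), float(areas.max())
    cm = colormaps[cmap]
    for rec in records:
        t = 0.5 if vmax == vmin else (rec.area_um2 - vmin) / (vmax - vmin)
        color = (np.asarray(cm(t))[:3] * 255).astype(np.uint8)
        rows, cols = rec.expanded_pixels if (expanded and rec.expanded_pixels
                                             is not None) else rec.pixels
        rgb[rows, cols] = color
    return rgb, (vmin, vmax)


def save_csa_legend(path: str | Path, vmin: float, vmax: float,
                    cmap: str = "viridis") -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 0.8))
    grad = np.linspace(0, 1, 256)[None, :]
    ax.imshow(grad, aspect="auto", cmap=cmap, extent=[vmin, vmax, 0, 1])
    ax.set_yticks([])
    ax.set_xlabel("CSA (um^2)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# section summary


@dataclass
class SectionSummary:
    n_fibers: int
    counts: dict[str, int]
    proportions: dict[str, float]
    mean_csa_um2: float
    mean_csa_by_type: dict[str, float]
    total_section_area_mm2: float
    sum_fiber_csa_mm2: float = 0.0
    stain_ratio: float | None = None
    stain_label: str | None = None
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "type": lab,
                "count": self.counts[lab],
                "proportion": self.proportions[lab],
                "mean_csa_um2": self.mean_csa_by_type.get(lab, np.nan),
            }
            for lab in FIBER_LABELS
        ]
        return pd.DataFrame(rows)

    def log_text(self) -> str:
        lines = [f"fibers analyzed: {self.n_fibers}"]
        for lab in ("I", "IIa", "IIb", "IIx"):
            lines.append(
                f"type {lab}: {self.counts[lab]} ({100 * self.proportions[lab]:.1f}%)"
            )
        mixed = sum(self.counts[lab] for lab in FIBER_LABELS
                    if "/" in lab)
        lines.append(f"mixed fibers: {mixed}")
        lines.append(f"total section size: {self.total_section_area_mm2:.3f} mm^2")
        lines.append(f"sum of fiber CSAs: {self.sum_fiber_csa_mm2:.3f} mm^2")
        lines.append(f"average CSA: {self.mean_csa_um2:.1f} um^2")
        if self.stain_ratio is not None:
            lines.append(
                f"stain quality: {self.stain_ratio:.2f} ({self.stain_label})"
            )
        return "\n".join(lines)


def summarize(records, calls, tissue_area_mm2: float) -> SectionSummary:
    """Counts, proportions and mean CSA per final type; validates the
    partition of gated fibers over the 8 categories."""
    ids = {rec.id for rec in records}
    if set(calls.labels) != ids:
        raise MyosegError("type calls do not partition the gated fibers")
    counts = calls.counts()
    if sum(counts.values()) != len(records):
        raise MyosegError("category counts do not sum to the fiber count")
    n = len(records)
    props = calls.proportions()
    areas = np.array([rec.area_um2 for rec in records]) if n else np.empty(0)
    by_type: dict[str, float] = {}
    for lab in FIBER_LABELS:
        sub = [rec.area_um2 for rec in records if calls.labels[rec.id] == lab]
        if sub:
            by_type[lab] = float(np.mean(sub))
    return SectionSummary(
        n_fibers=n,
        counts=counts,
        proportions=props,
        mean_csa_um2=float(areas.mean()) if n else 0.0,
        mean_csa_by_type=by_type,
        total_section_area_mm2=float(tissue_area_mm2),
        sum_fiber_csa_mm2=float(areas.sum()) * 1e-6,
    )
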