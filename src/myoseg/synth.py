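"""Synthetic muscle-section generator with full ground truth.

A transverse muscle section is emulated as a packing of convex polygonal
fibers: lognormal target cross-sectional areas are drawn, seed points are
placed by dart throwing inside an elliptical tissue region sized to hold them,
and a Laguerre (power) diagram — iteratively reweighted so cell areas match
the targets — tessellates the tissue into contiguous cells.  Cell cracks are
widened into a bright laminin boundary band of controllable width and
boundary:interior intensity ratio (the stain-quality ratio); each fiber's MyHC
type is sampled from the requested proportions (with a configurable fraction
of mixed fibers lighting two or three channels) and rendered into the
corresponding type channels; Gaussian noise is added everywhere.

The generator reproduces the geometry and contrast structure the pipeline
must handle — contiguous polygonal fibers, thin bright boundaries, per-type
channel intensities — not photorealistic microscopy (no PSF, vignetting or
stitching seams).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import LAMININ, MultiChannelImage, MyosegError
from .extract import FiberRecord

_MEMBER_KEYS = ("I", "IIa", "IIb")
_KEY_TO_CHANNEL = {"I": "type_I", "IIa": "type_IIa", "IIb": "type_IIb"}


@dataclass
class SynthSpec:
    """Study conditions for one synthetic section.

    Defaults emulate a good-quality 16-bit mouse section imaged at 10×:
    0.65 µm pixels, ~300 fibers of median CSA 900 µm² (lognormal, sigma 0.35),
    a 3 px laminin boundary at 6× the intra-fiber intensity, and fiber-type
    proportions typical of gastrocnemius.
    """

    shape: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.65
    n_fibers: int = 300
    csa_median_um2: float = 900.0
    csa_sigma: float = 0.35
    boundary_width_px: float = 3.0
    interior_level: float = 2000.0
    stain_ratio: float = 6.0
    noise_sd: float = 50.0
    background_level: float = 200.0
    type_proportions: dict[str, float] = field(
        default_factory=lambda: {"I": 0.10, "IIa": 0.30, "IIb": 0.40, "IIx": 0.20}
    )
    mixed_fraction: float = 0.01
    channel_positive_level: float = 12000.0
    channel_negative_level: float = 1000.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_proportions.values()) - 1.0) > 1e-9:
            raise MyosegError("type proportions must sum to 1")
        if self.stain_ratio <= 1:
            raise MyosegError("stain ratio must exceed 1")


@dataclass
class GTFiber:
    id: int
    csa_um2: float
    centroid: tuple[float, float]
    memberships: dict[str, bool]
    label: str
    polygon: np.ndarray | None = None  # boundary vertex estimate (row, col)


@dataclass
class GroundTruth:
    fibers: list[GTFiber]
    label_image: np.ndarray  # -1 background, else fiber id (1-based)
    pixel_classes: np.ndarray  # 0 outside tissue, 1 boundary, 2 intra-fiber
    spec: SynthSpec

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)

    def interior_pixels(self, fid: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero((self.label_image == fid) & (self.pixel_classes == 2))

    def annotation_mask(self, n_per_class: int = 400, seed: int = 0) -> np.ndarray:
        """Sparse two-class training annotations sampled from the truth."""
        rng = np.random.default_rng(seed)
        out = np.zeros(self.pixel_classes.shape, dtype=np.uint8)
        for cls in (1, 2):
            rr, cc = np.nonzero(self.pixel_classes == cls)
            take = min(n_per_class, rr.size)
            idx = rng.choice(rr.size, size=take, replace=False)
            out[rr[idx], cc[idx]] = cls
        return out


# ---------------------------------------------------------------------------
# geometry helpers


def _place_seeds(rng, radii_px: np.ndarray, center, axes,
                 overlap: float = 0.72, max_tries: int = 4000) -> np.ndarray:
    """Dart-throwing placement inside an ellipse with radius-aware spacing."""
    n = radii_px.size
    pts = np.empty((n, 2))
    placed = 0
    tree_pts: list[tuple[float, float]] = []
    order = np.argsort(radii_px)[::-1]  # place big fibers first
    radii_sorted = radii_px[order]
    for i in range(n):
        r_i = radii_sorted[i]
        ok = False
        for _ in range(max_tries):
            # uniform point in the ellipse, shrunk so the cell fits inside
            u, v = rng.random(), rng.random()
            rho, th = np.sqrt(u), 2 * np.pi * v
            shrink_r = max(axes[0] - 0.55 * r_i, 1.0)
            shrink_c = max(axes[1] - 0.55 * r_i, 1.0)
            p = (center[0] + shrink_r * rho * np.cos(th),
                 center[1] + shrink_c * rho * np.sin(th))
            if tree_pts:
                d = np.hypot(np.array(tree_pts)[:, 0] - p[0],
                             np.array(tree_pts)[:, 1] - p[1])
                min_req = overlap * (radii_sorted[:len(tree_pts)] + r_i)
                if (d < min_req).any():
                    continue
            tree_pts.append(p)
            ok = True
            break
        if not ok:
            raise MyosegError(
                f"n_fibers infeasible for image size: placed {placed} of {n} "
                "seeds before running out of room"
            )
        placed += 1
    pts[order] = np.array(tree_pts)
    return pts


def _power_labels(shape, inside, seeds, weights, k: int = 24) -> np.ndarray:
    """Per-pixel Laguerre assignment: argmin(d^2 - w) over nearby seeds."""
    h, w = shape
    labels = np.full(shape, -1, dtype=np.int32)
    rr, cc = np.nonzero(inside)
    pix = np.stack([rr, cc], axis=1).astype(np.float64)
    tree = cKDTree(seeds)
    k = min(k, len(seeds))
    dists, idx = tree.query(pix, k=k)
    if k == 1:
        dists, idx = dists[:, None], idx[:, None]
    power = dists**2 - weights[idx]
    owner = idx[np.arange(len(pix)), np.argmin(power, axis=1)]
    labels[rr, cc] = owner
    return labels


def _boundary_band(labels: np.ndarray, width_px: float) -> np.ndarray:
    """Pixels within width/2 of a label crack (tissue rim included)."""
    r = width_px / 2.0
    ri = int(np.ceil(r))
    dr, dc = np.mgrid[-ri:ri + 1, -ri:ri + 1]
    foot = (dr**2 + dc**2) <= r**2 + 1e-9
    lmax = ndimage.maximum_filter(labels, footprint=foot)
    lmin = ndimage.minimum_filter(labels, footprint=foot)
    return (lmax != lmin)


def _sample_memberships(rng, proportions: dict[str, float],
                        mixed_fraction: float) -> tuple[dict[str, bool], str]:
    base = rng.choice(list(proportions), p=list(proportions.values()))
    members = {k: False for k in _MEMBER_KEYS}
    if base == "IIx":
        return members, "IIx"  # IIx-containing hybrids are not emulated
    members[base] = True
    label = base
    if rng.random() < mixed_fraction:
        partners = {
            "I": ["IIa", "IIb"],
            "IIa": ["I", "IIb"],
            "IIb": ["I", "IIa"],
        }[base]
        # triples are rare even among hybrids
        if rng.random() < 0.1:
            extra = partners
        else:
            extra = [partners[int(rng.integers(len(partners)))]]
        for k in extra:
            members[k] = True
        on = [k for k in _MEMBER_KEYS if members[k]]
        label = "/".join(on)
    return members, label


# ---------------------------------------------------------------------------


def generate_section(spec: SynthSpec) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one annotated synthetic section; bit-identical for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    px = spec.pixel_size_um
    px_area = px * px

    # target areas (px^2) and the ellipse that exactly holds them
    areas_um2 = spec.csa_median_um2 * np.exp(
        spec.csa_sigma * rng.standard_normal(spec.n_fibers)
    )
    areas_px = areas_um2 / px_area
    total_px = areas_px.sum()
    max_a, max_b = (h - 16) / 2.0, (w - 16) / 2.0
    scale = np.sqrt(total_px / (np.pi * max_a * max_b))
    if scale > 1.0:
        raise MyosegError(
            "n_fibers infeasible for image size: requested fiber area exceeds "
            "the available tissue region"
        )
    axes = (max_a * scale, max_b * scale)
    center = ((h - 1) / 2.0, (w - 1) / 2.0)

    radii_px = np.sqrt(areas_px / np.pi)
    seeds = _place_seeds(rng, radii_px, center, axes)

    rr, cc = np.mgrid[0:h, 0:w]
    inside = (((rr - center[0]) / axes[0]) ** 2
              + ((cc - center[1]) / axes[1]) ** 2) <= 1.0

    # Laguerre weights tuned so realized cell areas track the targets;
    # early iterations also relax seeds toward cell centroids (Lloyd steps)
    # so squeezed cells can reach their target area
    weights = radii_px.astype(np.float64) ** 2
    coarse = 2 if min(h, w) >= 512 else 1
    ins_c = inside[::coarse, ::coarse]
    pr, pc = np.nonzero(ins_c)
    n_relax, n_iter = 12, 30
    for it in range(n_iter):
        lab_c = _power_labels(ins_c.shape, ins_c, seeds / coarse,
                              weights / coarse**2)
        flat = lab_c[lab_c >= 0]
        counts_c = np.bincount(flat, minlength=spec.n_fibers)
        got = counts_c * coarse**2
        if it < n_relax:
            sr = np.bincount(flat, weights=pr.astype(np.float64),
                             minlength=spec.n_fibers)
            sc = np.bincount(flat, weights=pc.astype(np.float64),
                             minlength=spec.n_fibers)
            nz = counts_c > 0
            seeds[nz, 0] = 0.7 * seeds[nz, 0] + 0.3 * (sr[nz] / counts_c[nz]) * coarse
            seeds[nz, 1] = 0.7 * seeds[nz, 1] + 0.3 * (sc[nz] / counts_c[nz]) * coarse
        weights += (areas_px - got) / np.pi
        weights = np.maximum(weights, 1.0)
    labels0 = _power_labels((h, w), inside, seeds, weights)

    # crack band between cells plus a full-width rim band inside the tissue
    # edge (the basement membrane wraps the outermost fibers completely)
    band = _boundary_band(labels0, spec.boundary_width_px)
    ri = int(np.ceil(spec.boundary_width_px))
    rim = inside & ~ndimage.binary_erosion(inside, iterations=ri)
    pixel_classes = np.zeros((h, w), dtype=np.uint8)
    pixel_classes[inside] = 2
    pixel_classes[(band | rim) & inside] = 1

    # ground-truth fibers; drop any seed that ended up with no pixels
    label_image = np.full((h, w), -1, dtype=np.int32)
    fibers: list[GTFiber] = []
    counts = np.bincount(labels0[labels0 >= 0], minlength=spec.n_fibers)
    next_id = 1
    for i in range(spec.n_fibers):
        if counts[i] == 0:
            continue
        sel = labels0 == i
        label_image[sel] = next_id
        frr, fcc = np.nonzero(sel)
        members, lab = _sample_memberships(rng, spec.type_proportions,
                                           spec.mixed_fraction)
        fibers.append(GTFiber(
            id=next_id,
            csa_um2=float(counts[i] * px_area),
            centroid=(float(frr.mean()), float(fcc.mean())),
            memberships=members,
            label=lab,
        ))
        next_id += 1

    # render channels
    hi = float(2**spec.bit_depth - 1)

    def _finish(plane: np.ndarray) -> np.ndarray:
        noisy = plane + rng.normal(0.0, spec.noise_sd, size=plane.shape)
        dt = np.uint8 if spec.bit_depth == 8 else np.uint16
        return np.clip(np.floor(noisy + 0.5), 0, hi).astype(dt)

    lam = np.full((h, w), spec.background_level)
    lam[pixel_classes == 2] = spec.interior_level
    lam[pixel_classes == 1] = spec.interior_level * spec.stain_ratio
    channels = {LAMININ: _finish(lam)}

    for key in _MEMBER_KEYS:
        ch = np.full((h, w), spec.background_level)
        ch[inside] = spec.channel_negative_level
        for fib in fibers:
            if fib.memberships[key]:
                sel = (label_image == fib.id) & (pixel_classes == 2)
                ch[sel] = spec.channel_positive_level
        channels[_KEY_TO_CHANNEL[key]] = _finish(ch)

    img = MultiChannelImage(channels=channels, pixel_size_um=px,
                            bit_depth=spec.bit_depth)
    gt = GroundTruth(fibers=fibers, label_image=label_image,
                     pixel_classes=pixel_classes, spec=spec)
    return img, gt


# ---------------------------------------------------------------------------
# detection scoring


@dataclass
class DetectionScore:
    n_truth: int
    n_pred: int
    matches: dict[int, int]  # truth id -> record id
    false_positives: list[tuple[int, str]]  # (record id, subclass)
    false_negatives: list[int]  # truth ids
    csa_errors: np.ndarray  # signed relative errors for matched fibers

    @property
    def fp_rate(self) -> float:
        return len(self.false_positives) / self.n_truth if self.n_truth else 0.0

    @property
    def fn_rate(self) -> float:
        return len(self.false_negatives) / self.n_truth if self.n_truth else 0.0

    @property
    def median_abs_csa_error(self) -> float:
        return float(np.median(np.abs(self.csa_errors))) if self.csa_errors.size else 0.0


def score_detection(records: list[FiberRecord], gt: GroundTruth,
                    iou_min: float = 0.5) -> DetectionScore:
    """Score detected fibers against ground truth by greedy IoU matching.

    Unmatched predictions are false positives, subclassified as "2 as 1"
    (one ROI spanning ≥2 truths), "1 as 2" (a sibling duplicate of an
    already-matched truth) or "non-fiber"; unmatched truths are false
    negatives.  Rates use the ground-truth fiber count as denominator.
    CSA errors are signed relative errors of matched records.

    Each record's mature (expanded) ROI — the pipeline's final fiber
    estimate — is compared against the truth when present; pre-expansion
    pixels are used otherwise.
    """
    truth = np.where(gt.pixel_classes == 2, gt.label_image, -1)
    gt_area = {f.id: int((truth == f.id).sum()) for f in gt.fibers}

    # per-record overlap counting (records may overlap one another, so no
    # shared prediction label plane is used)
    rec_area: dict[int, int] = {}
    ious = []
    overlap_by_pred: dict[int, list[tuple[int, int]]] = {}
    for rec in records:
        rows, cols = (rec.expanded_pixels if rec.expanded_pixels is not None
                      else rec.pixels)
        rec_area[rec.id] = rows.size
        vals = truth[rows, cols]
        hit = vals[vals > 0]
        if hit.size:
            tids, counts = np.unique(hit, return_counts=True)
            for t, n in zip(tids, counts):
                iou = n / (gt_area[int(t)] + rows.size - n)
                ious.append((float(iou), int(t), rec.id, int(n)))
                overlap_by_pred.setdefault(rec.id, []).append((int(t), int(n)))
    ious.sort(key=lambda x: (-x[0], x[1], x[2]))

    matches: dict[int, int] = {}
    used_pred: set[int] = set()
    for iou, t, p, _ in ious:
        if iou < iou_min:
            break
        if t in matches or p in used_pred:
            continue
        matches[t] = p
        used_pred.add(p)

    false_negatives = [f.id for f in gt.fibers if f.id not in matches]
    false_positives: list[tuple[int, str]] = []
    for rec in records:
        if rec.id in used_pred:
            continue
        overlaps = overlap_by_pred.get(rec.id, [])
        ts = [t for t, _ in overlaps]
        if len(ts) >= 2:
            union = sum(gt_area[t] for t in ts)
            inter_n = sum(n for _, n in overlaps)
            iou_u = inter_n / (union + rec_area[rec.id] - inter_n)
            if iou_u >= iou_min:
                false_positives.append((rec.id, "2 as 1"))
                continue
        best_t = max(overlaps, key=lambda x: x[1])[0] if overlaps else None
        if best_t is not None and best_t in matches:
            false_positives.append((rec.id, "1 as 2"))
        else:
            false_positives.append((rec.id, "non-fiber"))

    gt_by_id = {f.id: f for f in gt.fibers}
    errs = []
    for t, p in matches.items():
        rec = next(r for r in records if r.id == p)
        errs.append((rec.area_um2 - gt_by_id[t].csa_um2) / gt_by_id[t].csa_um2)
    return DetectionScore(
        n_truth=len(gt.fibers),
        n_pred=len(records),
        matches=matches,
        false_positives=false_positives,
        false_negatives=false_negatives,
        csa_errors=np.asarray(errs, dtype=np.float64),
    )


def score_typing(records: list[FiberRecord], calls, gt: GroundTruth,
                 det: DetectionScore) -> float:
    """Fraction of matched fibers whose final type call equals the truth."""
    if not det.matches:
        return 0.0
    gt_by_id = {f.id: f for f in gt.fibers}
    ok = sum(
        1 for t, p in det.matches.items() if calls.labels[p] == gt_by_id[t].label
    )
    return ok / len(det.matches)
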