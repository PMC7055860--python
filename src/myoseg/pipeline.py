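"""End-to-end orchestration of the full analysis pipeline.

preprocess → tile → primary + iterative classification → stitch → blur +
maximum-entropy threshold → particle extraction → morphometric gating → ROI
expansion → per-channel intensity statistics → fiber typing → summary.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import extract, fibertype, preprocess, report, segment
from .io import (AnnotationMask, MultiChannelImage, MyosegError, RunConfig,
                 write_fiber_tables, write_label_mask)

log = logging.getLogger("myoseg")


@dataclass
class PipelineResult:
    records: list  # kept fibers (post-expansion morphometrics)
    rejected: list  # (record, first failing gate)
    calls: fibertype.TypeCallTable
    summary: report.SectionSummary
    probmap: segment.ProbMap
    binary: np.ndarray
    threshold: int
    timings: dict[str, float] = field(default_factory=dict)


def train_classifiers(img: MultiChannelImage, annotations: AnnotationMask,
                      cfg: RunConfig, fc: segment.FeatureConfig | None = None
                      ) -> tuple[segment.PixelClassifier, segment.PixelClassifier]:
    """Train the primary (raw) and iterative (probmap) classifiers from one
    annotated section; both see the same sparse class annotations."""
    annotations.require_both_classes()
    fc = fc or segment.FeatureConfig()
    plane = preprocess.preprocess_boundary_channel(img.laminin, cfg.saturated_fraction)
    primary = segment.train_classifier([plane], [annotations], fc, domain="raw",
                                       n_trees=cfg.n_trees, seed=cfg.seed)
    pm = segment.classify(plane, primary)
    iterative = segment.train_classifier([pm.values], [annotations], fc,
                                         domain="probmap", n_trees=cfg.n_trees,
                                         seed=cfg.seed + 1)
    return primary, iterative


def segment_image(img: MultiChannelImage, primary: segment.PixelClassifier,
                  iterative: segment.PixelClassifier | None,
                  cfg: RunConfig) -> segment.ProbMap:
    """Preprocess the laminin channel, classify tile-by-tile and stitch."""
    plane = preprocess.preprocess_boundary_channel(img.laminin, cfg.saturated_fraction)
    ts = preprocess.tile_image(plane, cfg.grid_factor)
    pm_tiles = segment.classify_tiled_plane(
        plane, ts.offsets, [t.shape for t in ts.tiles], primary, iterative
    )
    stitched = preprocess.stitch(
        preprocess.TileSet(tiles=pm_tiles, offsets=ts.offsets,
                           grid_factor=ts.grid_factor, parent_shape=ts.parent_shape)
    )
    return segment.ProbMap(values=stitched)


def run_pipeline(img: MultiChannelImage, primary: segment.PixelClassifier,
                 iterative: segment.PixelClassifier | None, cfg: RunConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis on one multi-channel image."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    pm = segment_image(img, primary, iterative, cfg)
    timings["segmentation_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    blurred = pm.values.astype(np.float64)
    if cfg.gaussian_sigma_post > 0:
        from scipy import ndimage as ndi

        blurred = ndi.gaussian_filter(blurred, cfg.gaussian_sigma_post)
    hist = np.bincount(
        np.clip(np.floor(blurred + 0.5), 0, 255).astype(np.int64).ravel(),
        minlength=256,
    )[:256]
    t = extract.max_entropy_threshold(hist)
    binary = blurred > t
    rois = extract.extract_particles(binary, cfg.gate.exclude_edge_fibers)
    records = extract.measure_records(rois, img.pixel_size_um)
    kept, rejected = extract.apply_gates(records, cfg.gate)
    extract.expand_records(kept, cfg.gate.roi_expand_px, img.shape,
                           img.pixel_size_um)
    timings["extraction_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    calls = fibertype.call_types(kept, img, cfg.thresholds)
    timings["typing_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tissue = report.tissue_mask(img.laminin)
    area_mm2 = float(tissue.sum()) * img.pixel_size_um**2 * 1e-6
    summary = report.summarize(kept, calls, area_mm2)
    try:
        # the classifier's own boundary call (P(boundary) > 0.5) is the
        # tightest available boundary mask; the blurred/thresholded mask
        # would bleed into intra-fiber space and flatten the ratio
        ratio, quality = report.stain_quality(img, pm.values <= 127)
        summary.stain_ratio, summary.stain_label = ratio, quality
    except MyosegError:
        pass
    timings["reporting_s"] = time.perf_counter() - t0

    result = PipelineResult(records=kept, rejected=rejected, calls=calls,
                            summary=summary, probmap=pm, binary=binary,
                            threshold=t, timings=timings)
    if outdir is not None:
        _write_outputs(result, img, Path(outdir))
    for stage, secs in timings.items():
        log.info("%s: %.2f s", stage, secs)
    log.info("%s", summary.log_text())
    return result


def _write_outputs(res: PipelineResult, img: MultiChannelImage, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fiber_tables(res.records, res.calls, outdir)
    write_label_mask(outdir / "labels_pre_expansion.tif", res.records, img.shape)
    write_label_mask(outdir / "labels_post_expansion.tif", res.records, img.shape,
                     expanded=True)
    import pandas as pd

    pd.DataFrame(
        [{"id": rec.id, "reason": reason, "area_um2": rec.area_um2,
          "circularity": rec.circularity, "min_feret_um": rec.min_feret_um,
          "feret_ar": rec.feret_ar}
         for rec, reason in res.rejected]
    ).to_csv(outdir / "rejected.csv", index=False)
    res.summary.to_frame().to_csv(outdir / "summary.csv", index=False)
    (outdir / "run_log.txt").write_text(res.summary.log_text() + "\n")
    rgb, (vmin, vmax) = report.csa_map(res.records, img.shape, expanded=True)
    import tifffile

    tifffile.imwrite(outdir / "csa_map.tif", rgb)
    report.save_csa_legend(outdir / "csa_map_legend.png", vmin, vmax)
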