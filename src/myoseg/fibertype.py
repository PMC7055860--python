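"""MyHC fiber typing: intensity thresholding plus the black-and-white-mask /
modal-value procedure that resolves mixed fibers and type IIx.

Per channel (type I, IIa, IIb) each gated fiber is called positive when its
mean ROI intensity strictly exceeds the channel threshold.  Mixed fibers are
then found by rendering each positive set as a black-on-white binary mask and
probing other sets' ROIs for a modal value of 0 (black = overlap); pure fibers
are the positives whose ROI stays white over the merged masks of their mixed
combinations, and IIx fibers — detectable only by elimination — are the gated
fibers left white by the merged mask of all three positive sets.  The result
partitions the gated fibers over 8 categories: I, IIa, IIb, IIx, I/IIa, I/IIb,
IIa/IIb and I/IIa/IIb.

Masks are built from pre-expansion ROIs (which are disjoint), so the modal
procedure agrees exactly with direct set algebra; expanded (possibly
overlapping) ROIs are used only for intensity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FIBER_LABELS, MultiChannelImage, MyosegError, TYPE_CHANNELS
from .extract import FiberRecord
from .report import fd_bin_width

_MEMBER_KEYS = ("I", "IIa", "IIb")
_CHANNEL_TO_KEY = {"type_I": "I", "type_IIa": "IIa", "type_IIb": "IIb"}


@dataclass
class ChannelThreshold:
    channel: str
    mode: str  # "manual" | "auto"
    value: float
    #: (bin_edges, counts) Freedman–Diaconis histogram of the per-fiber means
    histogram: tuple[np.ndarray, np.ndarray] | None = None


@dataclass
class TypeCallTable:
    """Per-fiber memberships, final labels and the thresholds used."""

    labels: dict[int, str]
    memberships: dict[int, dict[str, bool]]
    thresholds: dict[str, ChannelThreshold] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        c = {lab: 0 for lab in FIBER_LABELS}
        for lab in self.labels.values():
            c[lab] += 1
        return c

    def proportions(self) -> dict[str, float]:
        n = len(self.labels)
        return {lab: (c / n if n else 0.0) for lab, c in self.counts().items()}


# ---------------------------------------------------------------------------


def roi_channel_stats(records: list[FiberRecord], img: MultiChannelImage,
                      channels: list[str] | None = None) -> list[FiberRecord]:
    """Fill per-channel mean/sd/min/max/mode over each fiber's expanded ROI.

    sd is the population standard deviation; mode is the most frequent integer
    value, smallest value winning ties.  Falls back to the pre-expansion pixel
    set when no expansion has been applied.
    """
    channels = channels or list(img.channels)
    h, w = img.shape
    for rec in records:
        rows, cols = rec.expanded_pixels if rec.expanded_pixels is not None else rec.pixels
        if rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w:
            raise MyosegError(f"fiber {rec.id} ROI outside image bounds")
        for name in channels:
            if name not in img.channels:
                raise MyosegError(f"channel {name!r} missing from image")
            vals = img.channels[name][rows, cols]
            counts = np.bincount(vals.astype(np.int64))
            rec.channel_stats[name] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std()),  # population
                "min": float(vals.min()),
                "max": float(vals.max()),
                "mode": float(np.argmax(counts)),  # argmax → smallest on ties
            }
    return records


def _otsu_split(values: np.ndarray) -> float:
    """Exhaustive Otsu split of a 1-D sample: threshold between the two
    classes maximizing between-class variance, placed at the midpoint of the
    optimal cut."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    n = v.size
    best, best_k = -np.inf, None
    csum = np.cumsum(v)
    total = csum[-1]
    for k in range(1, n):  # lower class = v[:k]
        w0, w1 = k, n - k
        m0 = csum[k - 1] / w0
        m1 = (total - csum[k - 1]) / w1
        score = w0 * w1 * (m0 - m1) ** 2
        if score > best:
            best, best_k = score, k
    return float((v[best_k - 1] + v[best_k]) / 2.0)


def choose_threshold(values, mode: str, manual_value: float | None = None,
                     channel: str = "") -> ChannelThreshold:
    """Pick an intensity threshold for one type channel.

    ``manual`` returns the user's value (the standard interactive flow);
    ``auto`` is an extension that takes the Otsu split of the per-fiber mean
    intensity distribution.  A Freedman–Diaconis histogram of the values is
    attached for inspection either way.
    """
    values = np.asarray(list(values), dtype=np.float64)
    if values.size < 1:
        raise MyosegError("need at least one intensity value")
    if mode == "manual":
        if manual_value is None:
            raise MyosegError("manual threshold mode requires a value")
        thr = float(manual_value)
    elif mode == "auto":
        if values.size < 2 or np.ptp(values) == 0:
            raise MyosegError("auto threshold needs >=2 distinct values to split")
        thr = _otsu_split(values)
    else:
        raise MyosegError(f"unknown threshold mode {mode!r}")
    if values.size >= 2:
        width = fd_bin_width(values)
        lo, hi = values.min(), values.max()
        nbins = max(1, int(np.ceil((hi - lo) / width))) if hi > lo else 1
        counts, edges = np.histogram(values, bins=nbins, range=(lo, hi if hi > lo else lo + 1))
        hist = (edges, counts)
    else:
        hist = None
    return ChannelThreshold(channel=channel, mode=mode, value=thr, histogram=hist)


def positive_set(records: list[FiberRecord], channel: str,
                 thr: ChannelThreshold) -> set[int]:
    """Fibers whose mean intensity on ``channel`` strictly exceeds the threshold."""
    out = set()
    for rec in records:
        if channel not in rec.channel_stats:
            raise MyosegError(f"fiber {rec.id} lacks stats for channel {channel!r}")
        if rec.channel_stats[channel]["mean"] > thr.value:
            out.add(rec.id)
    return out


# ---------------------------------------------------------------------------
# black-and-white mask / modal machinery


def bw_mask(selected: set[int], records: list[FiberRecord],
            shape: tuple[int, int]) -> np.ndarray:
    """Selected ROIs filled black (0) on a white (255) background."""
    mask = np.full(shape, 255, dtype=np.uint8)
    by_id = {rec.id: rec for rec in records}
    for fid in selected:
        rows, cols = by_id[fid].pixels
        mask[rows, cols] = 0
    return mask


def modal_select(mask: np.ndarray, probe: set[int], records: list[FiberRecord],
                 target: int) -> set[int]:
    """Probe fibers whose modal mask value within their ROI equals ``target``.

    Mask values are 0/255; an exact black/white tie resolves to 0 (the first
    modal bin of an integer histogram).
    """
    if target not in (0, 255):
        raise MyosegError("target must be 0 or 255")
    by_id = {rec.id: rec for rec in records}
    out = set()
    for fid in probe:
        rows, cols = by_id[fid].pixels
        if rows.max() >= mask.shape[0] or cols.max() >= mask.shape[1]:
            raise MyosegError("mask geometry does not match ROI coordinates")
        vals = mask[rows, cols]
        n_black = int(np.count_nonzero(vals == 0))
        n_white = int(vals.size - n_black)
        mode = 0 if n_black >= n_white else 255  # tie → 0
        if mode == target:
            out.add(fid)
    return out


def classify_fibers(records: list[FiberRecord], pos_I: set[int], pos_IIa: set[int],
                    pos_IIb: set[int], shape: tuple[int, int] | None = None,
                    thresholds: dict[str, ChannelThreshold] | None = None
                    ) -> TypeCallTable:
    """Assign final labels via the black-and-white-mask modal procedure.

    Pairwise masks yield mixed sets, the triple overlap yields I/IIa/IIb, each
    pure type is its positive set stripped of its mixed combinations, and IIx
    is everything left unstained.  The result is validated to partition the
    gated fibers.
    """
    all_ids = {rec.id for rec in records}
    for name, s in (("pos_I", pos_I), ("pos_IIa", pos_IIa), ("pos_IIb", pos_IIb)):
        if not s <= all_ids:
            raise MyosegError(f"{name} references unknown fiber ids: {s - all_ids}")
    if shape is None:
        h = max((int(r.pixels[0].max()) for r in records), default=0) + 1
        w = max((int(r.pixels[1].max()) for r in records), default=0) + 1
        shape = (h, w)
    pos = {"I": pos_I, "IIa": pos_IIa, "IIb": pos_IIb}

    # pairwise mixed sets: probe A over the black mask of B
    mixed: dict[frozenset, set[int]] = {}
    for a, b in (("I", "IIa"), ("I", "IIb"), ("IIa", "IIb")):
        mixed[frozenset((a, b))] = modal_select(
            bw_mask(pos[b], records, shape), pos[a], records, target=0
        )
    # triple overlap: probe I over the mask of the IIa/IIb mixed set
    triple = modal_select(
        bw_mask(mixed[frozenset(("IIa", "IIb"))], records, shape), pos["I"],
        records, target=0,
    )
    # pure types: positives whose ROI stays white over their merged mixed masks
    pure: dict[str, set[int]] = {}
    for key in _MEMBER_KEYS:
        mixed_union: set[int] = set(triple)
        for pair, ids in mixed.items():
            if key in pair:
                mixed_union |= ids
        pure[key] = modal_select(
            bw_mask(mixed_union, records, shape), pos[key], records, target=255
        )
    # IIx by elimination: gated fibers left white by all three positive masks
    iix = modal_select(
        bw_mask(pos_I | pos_IIa | pos_IIb, records, shape), all_ids, records,
        target=255,
    )

    labels: dict[int, str] = {}
    for fid in iix:
        labels[fid] = "IIx"
    for key, ids in pure.items():
        for fid in ids:
            _assign(labels, fid, key)
    pair_name = {frozenset(("I", "IIa")): "I/IIa",
                 frozenset(("I", "IIb")): "I/IIb",
                 frozenset(("IIa", "IIb")): "IIa/IIb"}
    for pair, ids in mixed.items():
        for fid in ids - triple:
            _assign(labels, fid, pair_name[pair])
    for fid in triple:
        _assign(labels, fid, "I/IIa/IIb")

    missing = all_ids - set(labels)
    if missing:
        raise MyosegError(f"fibers received no final label: {sorted(missing)}")
    memberships = {
        rec.id: {key: rec.id in pos[key] for key in _MEMBER_KEYS} for rec in records
    }
    return TypeCallTable(labels=labels, memberships=memberships,
                         thresholds=thresholds or {})


def _assign(labels: dict[int, str], fid: int, label: str) -> None:
    if fid in labels:
        raise MyosegError(
            f"fiber {fid} assigned two final labels ({labels[fid]} and {label}): "
            "partition invariant violated"
        )
    labels[fid] = label


def call_types(records: list[FiberRecord], img: MultiChannelImage,
               thresholds: dict[str, float | str]) -> TypeCallTable:
    """Convenience wrapper: stats → thresholds → positive sets → final calls.

    ``thresholds`` maps type-channel names to a numeric manual value or
    ``"auto"``; channels absent from the image are treated as all-negative.
    """
    roi_channel_stats(records, img)
    pos: dict[str, set[int]] = {k: set() for k in _MEMBER_KEYS}
    thr_used: dict[str, ChannelThreshold] = {}
    for ch in TYPE_CHANNELS:
        if ch not in img.channels:
            continue
        spec = thresholds.get(ch, "auto")
        means = [rec.channel_stats[ch]["mean"] for rec in records]
        if not means:
            continue
        if spec == "auto":
            thr = choose_threshold(means, "auto", channel=ch)
        else:
            thr = choose_threshold(means, "manual", manual_value=float(spec), channel=ch)
        thr_used[ch] = thr
        pos[_CHANNEL_TO_KEY[ch]] = positive_set(records, ch, thr)
    return classify_fibers(records, pos["I"], pos["IIa"], pos["IIb"],
                           shape=None, thresholds=thr_used)
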