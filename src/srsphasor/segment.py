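"""Phasor-plot gating, clustering, back-mapping, and per-segment spectra.

Segmentation happens in phasor space: a gate is a polygon in the (G, S)
plane, and every pixel whose phasor falls inside it joins the corresponding
image segment. Gates may be drawn explicitly (mirroring the manual
"coloured boxes" workflow of phasor analysis) or derived automatically by
seeded k-means over the valid-pixel phasor cloud, which makes the gating
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from scipy.optimize import linear_sum_assignment
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon
from sklearn.cluster import KMeans

from .errors import DegenerateInputError, DomainError, ValidationError
from .hyperstack import HyperStack, SegmentLabelImage
from .phasor import PhasorField

__all__ = [
    "PhasorGate",
    "SegmentSpectraTable",
    "MatchReport",
    "gate_segment",
    "auto_cluster",
    "segment_spectra",
    "match_segments",
    "render_composite",
    "box_gate",
    "read_gates",
    "write_gates",
]

# distinguishable default palette for up to 12 segments (RGB, 0-255)
_PALETTE: tuple[tuple[int, int, int], ...] = (
    (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
    (210, 245, 60), (250, 190, 212), (0, 128, 128), (220, 190, 255),
)


@dataclass(frozen=True)
class PhasorGate:
    """A named, simple polygon in (G, S) space; higher priority wins overlaps."""

    name: str
    polygon: tuple[tuple[float, float], ...]
    priority: int
    color: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        object.__setattr__(self, "polygon", tuple(tuple(map(float, v)) for v in self.polygon))
        object.__setattr__(self, "color", tuple(int(c) for c in self.color))
        if len(self.polygon) < 3:
            raise ValidationError(f"gate {self.name!r} needs >= 3 vertices")
        if not Polygon(self.polygon).is_valid:
            raise ValidationError(f"gate {self.name!r} polygon is self-intersecting")

    def contains(self, g: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Vectorized point-in-polygon; points on an edge count as inside."""
        return shapely.intersects_xy(Polygon(self.polygon), np.asarray(g), np.asarray(s))


@dataclass(frozen=True)
class SegmentSpectraTable:
    """Per-segment pixel counts plus mean and min-max normalized spectra."""

    wavenumbers: np.ndarray
    names: tuple[str, ...]
    pixel_counts: tuple[int, ...]
    mean_spectra: np.ndarray       # (n_segments, n_frames); NaN rows for empty segments
    normalized_spectra: np.ndarray

    def is_empty(self, i: int) -> bool:
        return self.pixel_counts[i] == 0

    def to_frame(self):
        import pandas as pd

        data = {"wavenumber_cm1": self.wavenumbers}
        for i, name in enumerate(self.names):
            data[name] = self.normalized_spectra[i]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class MatchReport:
    """Optimal one-to-one matching of recovered segments to truth classes."""

    pairs: tuple[tuple[str, str], ...]  # (segment name, truth class name)
    ious: tuple[float, ...]
    iou_threshold: float

    @property
    def n_matched(self) -> int:
        return sum(1 for iou in self.ious if iou >= self.iou_threshold)

    def per_class(self) -> dict[str, float]:
        return {truth: iou for (_, truth), iou in zip(self.pairs, self.ious)}


def box_gate(
    name: str,
    center: tuple[float, float],
    half_width: float,
    priority: int,
    color: tuple[int, int, int] = (255, 255, 255),
) -> PhasorGate:
    """Axis-aligned square gate around a phasor point (a 'coloured box')."""
    g, s = center
    h = half_width
    return PhasorGate(
        name=name,
        polygon=((g - h, s - h), (g + h, s - h), (g + h, s + h), (g - h, s + h)),
        priority=priority,
        color=color,
    )


def gate_segment(field: PhasorField, gates: list[PhasorGate]) -> SegmentLabelImage:
    """Back-map phasor gates to an image segment label per pixel.

    Each valid pixel takes the label of the highest-priority gate containing
    its (G, S) point; ungated and invalid pixels get label 0. Labels are
    assigned 1..K in the order the gates are given.
    """
    names = [g.name for g in gates]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate gate names: {names}")
    priorities = [g.priority for g in gates]
    if len(set(priorities)) != len(priorities):
        raise ValidationError("gate priorities must be unique")
    labels = np.zeros(field.G.shape, dtype=np.int32)
    gv = field.G[field.valid_mask]
    sv = field.S[field.valid_mask]
    chosen = np.zeros(len(gv), dtype=np.int32)
    # ascending priority: later (higher-priority) gates overwrite
    order = np.argsort(priorities, kind="stable")
    for gate_idx in order:
        inside = gates[gate_idx].contains(gv, sv)
        chosen[inside] = gate_idx + 1
    labels[field.valid_mask] = chosen
    return SegmentLabelImage(
        labels=labels,
        names={i + 1: g.name for i, g in enumerate(gates)},
        colors={i + 1: g.color for i, g in enumerate(gates)},
    )


def auto_cluster(field: PhasorField, k: int, seed: int) -> list[PhasorGate]:
    """Derive k phasor gates by seeded k-means over valid-pixel (G, S).

    Each cluster is returned as the convex hull of its member points, so the
    gates exactly cover the clustered pixels. Priorities are assigned by
    descending member count — the smallest cluster gets the highest
    priority, so compact minority populations are not swallowed where hulls
    overlap. Fixed seed makes the gating bit-reproducible.
    """
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    pts = field.valid_points()
    if len(pts) < k:
        raise DomainError(f"only {len(pts)} valid pixels for k={k}")
    if len(np.unique(pts, axis=0)) < k:
        raise DegenerateInputError(
            f"fewer than k={k} distinct phasor points; clustering is degenerate"
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    assign = km.fit_predict(pts)
    counts = np.bincount(assign, minlength=k)
    # descending member count -> priorities 1..k (largest first, smallest highest)
    by_size = np.argsort(-counts, kind="stable")
    priority_of = {int(c): rank + 1 for rank, c in enumerate(by_size)}
    gates = []
    for c in range(k):
        members = pts[assign == c]
        gates.append(
            PhasorGate(
                name=f"cluster_{c}",
                polygon=_hull_polygon(members),
                priority=priority_of[c],
                color=_PALETTE[c % len(_PALETTE)],
            )
        )
    return gates


def _hull_polygon(points: np.ndarray, pad: float = 1e-9) -> tuple[tuple[float, float], ...]:
    """Convex hull vertices; degenerate (collinear/tiny) clusters fall back
    to a padded bounding box so the gate remains a valid polygon."""
    try:
        hull = ConvexHull(points)
        return tuple(map(tuple, points[hull.vertices]))
    except (QhullError, ValueError):
        lo = points.min(axis=0) - pad
        hi = points.max(axis=0) + pad
        return ((lo[0], lo[1]), (hi[0], lo[1]), (hi[0], hi[1]), (lo[0], hi[1]))


def segment_spectra(stack: HyperStack, labels: SegmentLabelImage) -> SegmentSpectraTable:
    """Mean spectrum per segment, plus a min-max normalized copy.

    Empty segments are reported with pixel_count 0 and NaN spectra rather
    than dropped, so gating errors stay visible. Spectra are returned in
    ascending wavenumber order.
    """
    if stack.intensities.shape[:2] != labels.labels.shape:
        raise ValidationError(
            f"stack image size {stack.intensities.shape[:2]} != "
            f"label image size {labels.labels.shape}"
        )
    order = stack.axis.ascending_order()
    cube = np.asarray(stack.intensities, dtype=float)[:, :, order]
    n_seg = labels.n_segments
    n_frames = cube.shape[2]
    flat_labels = labels.labels.ravel()
    flat = cube.reshape(-1, n_frames)
    counts = np.bincount(flat_labels, minlength=n_seg + 1)[1:]
    sums = np.zeros((n_seg, n_frames))
    for lab in range(1, n_seg + 1):
        if counts[lab - 1]:
            sums[lab - 1] = flat[flat_labels == lab].sum(axis=0)
    means = np.full((n_seg, n_frames), np.nan)
    normalized = np.full((n_seg, n_frames), np.nan)
    nonzero = counts > 0
    means[nonzero] = sums[nonzero] / counts[nonzero, None]
    for i in np.flatnonzero(nonzero):
        lo, hi = means[i].min(), means[i].max()
        normalized[i] = (means[i] - lo) / (hi - lo) if hi > lo else means[i] * 0.0
    return SegmentSpectraTable(
        wavenumbers=stack.axis.values[order],
        names=tuple(labels.names[i] for i in range(1, n_seg + 1)),
        pixel_counts=tuple(int(c) for c in counts),
        mean_spectra=means,
        normalized_spectra=normalized,
    )


def match_segments(
    labels: SegmentLabelImage,
    truth_masks: dict[str, np.ndarray],
    iou_threshold: float = 0.5,
) -> MatchReport:
    """Optimal one-to-one assignment of recovered segments to truth classes.

    Builds the full IoU matrix between every recovered segment and every
    ground-truth mask and solves the assignment maximizing total IoU
    (Hungarian algorithm). A truth class counts as recovered when its
    matched IoU reaches ``iou_threshold`` (0.5, the standard detection
    convention).
    """
    truth_names = list(truth_masks)
    seg_ids = sorted(labels.names)
    iou = np.zeros((len(seg_ids), len(truth_names)))
    for i, sid in enumerate(seg_ids):
        seg = labels.labels == sid
        seg_area = seg.sum()
        for j, tname in enumerate(truth_names):
            mask = np.asarray(truth_masks[tname], dtype=bool)
            if mask.shape != seg.shape:
                raise ValidationError("truth mask and label image sizes differ")
            inter = np.logical_and(seg, mask).sum()
            union = seg_area + mask.sum() - inter
            iou[i, j] = inter / union if union else 0.0
    rows, cols = linear_sum_assignment(iou, maximize=True)
    pairs = tuple((labels.names[seg_ids[r]], truth_names[c]) for r, c in zip(rows, cols))
    return MatchReport(
        pairs=pairs,
        ious=tuple(float(iou[r, c]) for r, c in zip(rows, cols)),
        iou_threshold=iou_threshold,
    )


def render_composite(
    labels: SegmentLabelImage,
    total_intensity: np.ndarray | None = None,
) -> np.ndarray:
    """RGB composite of a label image: each segment in its gate color on a
    black background, optionally modulated by normalized total intensity."""
    rows, cols = labels.labels.shape
    rgb = np.zeros((rows, cols, 3), dtype=float)
    for lab in labels.names:
        color = labels.colors.get(lab, _PALETTE[(lab - 1) % len(_PALETTE)])
        rgb[labels.labels == lab] = color
    if total_intensity is not None:
        ti = np.asarray(total_intensity, dtype=float)
        hi = ti.max()
        if hi > 0:
            rgb *= (ti / hi)[:, :, None]
    return np.clip(rgb, 0, 255).astype(np.uint8)


def write_gates(gates: list[PhasorGate], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {
                    "name": g.name,
                    "vertices": [list(v) for v in g.polygon],
                    "priority": g.priority,
                    "color": list(g.color),
                }
                for g in gates
            ],
            indent=1,
        )
    )


def read_gates(path: str | Path) -> list[PhasorGate]:
    data = json.loads(Path(path).read_text())
    return [
        PhasorGate(
            name=d["name"],
            polygon=tuple(tuple(v) for v in d["vertices"]),
            priority=d["priority"],
            color=tuple(d.get("color", (255, 255, 255))),
        )
        for d in data
    ]
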