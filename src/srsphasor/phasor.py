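"""Per-pixel spectral phasor transform of hyperspectral stacks.

The spectral phasor maps each pixel's spectrum ``I(k)`` (frames in
ascending-wavenumber order, ``k = 0..N-1``) to normalized first-harmonic
Fourier coefficients::

    G = sum_k I(k) cos(2 pi n k / N) / sum_k I(k)
    S = sum_k I(k) sin(2 pi n k / N) / sum_k I(k)

Pixels with similar spectral *shape* land at the same (G, S) point whatever
their brightness (the transform is scale-invariant), so chemically similar
regions cluster in phasor space and can be gated into image segments.

Multi-window acquisitions (e.g. the C-H window plus two cell-silent windows)
are concatenated frame-wise before the transform: the Fourier coordinate is
the frame index, not the physical wavenumber, i.e. windows are abutted. This
mirrors running the analysis "on the combined image stacks" and keeps the
transform deterministic without any gap-filling convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .hyperstack import HyperStack, WavenumberAxis

__all__ = [
    "PhasorField",
    "PhasorHistogram",
    "concat_windows",
    "phasor_transform",
    "phasor_of_mixture",
    "phasor_histogram",
    "DEFAULT_THRESHOLD_FRACTION",
]

#: Default intensity threshold, as a fraction of the maximum per-pixel total
#: intensity; pixels below it have a noise-dominated, undefined phasor.
DEFAULT_THRESHOLD_FRACTION = 0.01

_BOUND_EPS = 1e-9  # double-precision accumulation bound for G^2+S^2 <= 1


@dataclass(frozen=True)
class PhasorField:
    """Per-pixel (G, S) phasor coordinates with a validity mask.

    Invalid pixels (total intensity below threshold) carry (0, 0) and are
    excluded from histograms and segmentation; the explicit mask avoids NaN
    propagation through downstream stages.
    """

    G: np.ndarray
    S: np.ndarray
    total_intensity: np.ndarray
    harmonic: int
    valid_mask: np.ndarray
    intensity_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not (self.G.shape == self.S.shape == self.total_intensity.shape == self.valid_mask.shape):
            raise ValidationError("phasor planes must share one 2-D shape")
        r2 = self.G[self.valid_mask] ** 2 + self.S[self.valid_mask] ** 2
        if r2.size and float(r2.max()) > 1.0 + _BOUND_EPS:
            raise ValidationError("valid phasor points must satisfy G^2+S^2 <= 1")

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_points(self) -> np.ndarray:
        """(n_valid, 2) array of valid (G, S) points, row-major pixel order."""
        return np.column_stack([self.G[self.valid_mask], self.S[self.valid_mask]])


@dataclass(frozen=True)
class PhasorHistogram:
    """2-D histogram of valid-pixel (G, S) points on a fixed [-1, 1]^2 grid."""

    counts: np.ndarray
    bin_count: int

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(-1.0, 1.0, self.bin_count + 1)


def concat_windows(stacks: list[HyperStack]) -> HyperStack:
    """Concatenate acquisition windows frame-wise into one combined stack.

    Per-pixel spectra are concatenated with no resampling; each input keeps
    its window identity (re-tagged 0..n-1 in the given order so the combined
    axis stays valid). Windows must not overlap in wavenumber.
    """
    if not stacks:
        raise ValidationError("concat_windows requires at least one stack")
    if len(stacks) == 1:
        return stacks[0]
    shape = stacks[0].intensities.shape[:2]
    for s in stacks[1:]:
        if s.intensities.shape[:2] != shape:
            raise ValidationError(
                f"image size mismatch: {s.intensities.shape[:2]} vs {shape}"
            )
    ranges = []
    values, window_ids = [], []
    next_wid = 0
    for s in stacks:
        for wid, (lo, hi) in sorted(s.axis.window_ranges().items()):
            ranges.append((lo, hi))
        # re-tag windows consecutively in concatenation order
        local = s.axis.window_ids - s.axis.window_ids.min()
        # local ids are non-decreasing; compress to consecutive integers
        _, dense = np.unique(local, return_inverse=True)
        window_ids.append(dense + next_wid)
        next_wid += s.axis.n_windows
        values.append(s.axis.values)
    ranges.sort()
    for (lo1, hi1), (lo2, hi2) in zip(ranges, ranges[1:]):
        if hi1 >= lo2:
            raise ValidationError(
                f"windows overlap in wavenumber: [{lo1}, {hi1}] vs [{lo2}, {hi2}]"
            )
    axis = WavenumberAxis(
        values=np.concatenate(values),
        window_ids=np.concatenate(window_ids),
        step_nm=stacks[0].axis.step_nm,
    )
    return HyperStack(
        intensities=np.concatenate([s.intensities for s in stacks], axis=2), axis=axis
    )


def phasor_transform(
    stack: HyperStack,
    harmonic: int = 1,
    intensity_threshold: float | None = None,
) -> PhasorField:
    """Spectral phasor transform of every pixel of a stack.

    Parameters
    ----------
    stack
        Input stack; frames are sorted ascending in wavenumber internally.
    harmonic
        Fourier harmonic ``n`` (default 1, the standard choice: it gives the
        widest phasor spread for single broad spectral features).
    intensity_threshold
        Pixels whose summed intensity falls below this are marked invalid
        and assigned (0, 0). Default: 1% of the maximum per-pixel total.
    """
    if harmonic < 1:
        raise DomainError(f"harmonic must be >= 1, got {harmonic}")
    if stack.n_frames < 2:
        raise ValidationError("phasor transform needs at least 2 frames")

    order = stack.axis.ascending_order()
    cube = np.asarray(stack.intensities, dtype=float)[:, :, order]
    n = cube.shape[2]
    phase = 2.0 * np.pi * harmonic * np.arange(n) / n
    total = cube.sum(axis=2)
    if intensity_threshold is None:
        intensity_threshold = DEFAULT_THRESHOLD_FRACTION * float(total.max())
    valid = total >= intensity_threshold
    if not valid.any():
        warnings.warn("no pixel passes the intensity threshold; phasor field is empty")
    safe_total = np.where(valid, total, 1.0)
    G = np.where(valid, cube @ np.cos(phase) / safe_total, 0.0)
    S = np.where(valid, cube @ np.sin(phase) / safe_total, 0.0)
    return PhasorField(
        G=G,
        S=S,
        total_intensity=total,
        harmonic=harmonic,
        valid_mask=valid,
        intensity_threshold=float(intensity_threshold),
    )


def phasor_of_mixture(components: list[tuple[tuple[float, float], float]]) -> tuple[float, float]:
    """Predicted phasor of a sum of spectra from their individual phasors.

    The phasor transform is linear in intensity, so the phasor of a summed
    spectrum is the intensity-weighted mean of the component (G, S) points.
    ``components`` is a list of ``((G, S), total_intensity)`` pairs.
    """
    if not components:
        raise DomainError("mixture requires at least one component")
    weights = np.array([w for _, w in components], dtype=float)
    if np.any(weights < 0):
        raise DomainError("component intensities must be non-negative")
    if weights.sum() == 0:
        raise DomainError("mixture requires positive total intensity")
    points = np.array([p for p, _ in components], dtype=float)
    g, s = weights @ points / weights.sum()
    return float(g), float(s)


def phasor_histogram(field: PhasorField, bin_count: int) -> PhasorHistogram:
    """Histogram of valid-pixel (G, S) points on a bin_count^2 grid over [-1,1]^2."""
    if bin_count < 2:
        raise DomainError(f"bin_count must be >= 2, got {bin_count}")
    pts = field.valid_points()
    edges = np.linspace(-1.0, 1.0, bin_count + 1)
    counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=(edges, edges))
    return PhasorHistogram(counts=counts, bin_count=bin_count)
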