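"""Hyperspectral SRS stack data model and file I/O.

A hyperspectral stimulated-Raman-scattering (SRS) acquisition is a stack of
grayscale images, one per Raman shift, collected by re-tuning the pump laser
in small wavelength steps. On disk a stack is a multi-page grayscale TIFF
(one page per frame) with a JSON sidecar giving the wavenumber axis::

    {"wavenumbers": [...], "window_ids": [...], "step_nm": 0.4}

Frames are stored in acquisition order — descending wavenumber within each
window, matching pump-wavelength tuning — and spectral operations sort
ascending internally. Pixel coordinates are 0-based, row-major.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, DomainError, OutOfRangeError, ValidationError

__all__ = [
    "WavenumberAxis",
    "HyperStack",
    "Spectrum",
    "FrequencyImage",
    "SegmentLabelImage",
    "read_stack",
    "write_stack",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_label_image",
    "write_label_image",
    "pump_step_to_wavenumber_step",
    "extract_frequency_image",
]


@dataclass(frozen=True)
class WavenumberAxis:
    """Maps frame index to Raman shift (cm^-1) and acquisition window.

    Parameters
    ----------
    values
        One Raman shift per frame, strictly monotonic within each window
        (either direction; acquisition order is typically descending).
    window_ids
        Integer window tag per frame, non-decreasing over frame index.
    step_nm
        Nominal pump-tuning step in nm. Metadata only; never used in math.
    """

    values: np.ndarray
    window_ids: np.ndarray
    step_nm: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        window_ids = np.asarray(self.window_ids, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "window_ids", window_ids)
        if values.ndim != 1 or window_ids.ndim != 1:
            raise ValidationError("axis values and window_ids must be 1-D")
        if len(values) != len(window_ids):
            raise ValidationError(
                f"axis has {len(values)} wavenumbers but {len(window_ids)} window ids"
            )
        if len(values) == 0:
            raise ValidationError("axis must contain at least one frame")
        if not np.all(np.isfinite(values)):
            raise ValidationError("axis wavenumbers must be finite")
        if np.any(np.diff(window_ids) < 0):
            raise ValidationError("window_ids must be non-decreasing over frame index")
        for wid in np.unique(window_ids):
            v = values[window_ids == wid]
            d = np.diff(v)
            if len(d) and not (np.all(d > 0) or np.all(d < 0)):
                raise ValidationError(
                    f"wavenumbers not strictly monotonic within window {wid}"
                )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_windows(self) -> int:
        return len(np.unique(self.window_ids))

    def ascending_order(self) -> np.ndarray:
        """Frame permutation sorting wavenumbers ascending (stable).

        Windows never overlap in wavenumber, so a global sort also keeps
        frames of each window contiguous.
        """
        return np.argsort(self.values, kind="stable")

    def window_ranges(self) -> dict[int, tuple[float, float]]:
        """(lo, hi) wavenumber span per window id."""
        out: dict[int, tuple[float, float]] = {}
        for wid in np.unique(self.window_ids):
            v = self.values[self.window_ids == wid]
            out[int(wid)] = (float(v.min()), float(v.max()))
        return out


@dataclass(frozen=True)
class HyperStack:
    """A rows x cols x frames intensity cube bound to a wavenumber axis."""

    intensities: np.ndarray
    axis: WavenumberAxis

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        object.__setattr__(self, "intensities", arr)
        if arr.ndim != 3:
            raise ValidationError(
                f"intensities must be rows x cols x frames, got shape {arr.shape}"
            )
        if arr.shape[2] == 0:
            raise ValidationError("stack must contain at least one frame")
        if arr.shape[2] != len(self.axis):
            raise ValidationError(
                f"stack has {arr.shape[2]} frames but axis has {len(self.axis)} entries"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("stack intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[2]

    def pixel_spectrum(self, row: int, col: int) -> "Spectrum":
        """Spectrum at one pixel, sorted ascending in wavenumber."""
        order = self.axis.ascending_order()
        return Spectrum(
            wavenumbers=self.axis.values[order],
            intensities=np.asarray(self.intensities[row, col, order], dtype=float),
        )

    def nearest_frame_index(self, wavenumber: float) -> int:
        """Index of the frame nearest to ``wavenumber``; ties break toward
        the lower frame index. Raises if the request misses the axis by more
        than one scan step."""
        dist = np.abs(self.axis.values - wavenumber)
        idx = int(np.argmin(dist))  # argmin takes the first (lowest) index on ties
        steps = np.abs(np.diff(np.sort(self.axis.values)))
        max_step = float(steps.max()) if len(steps) else 0.0
        if dist[idx] > max_step and dist[idx] > 0:
            raise OutOfRangeError(
                f"{wavenumber} cm^-1 is {dist[idx]:.2f} cm^-1 from the nearest frame "
                f"({self.axis.values[idx]} cm^-1), more than one scan step"
            )
        return idx


@dataclass(frozen=True)
class Spectrum:
    """A single-point spectrum: wavenumbers (cm^-1) and intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", i)
        if w.ndim != 1 or i.ndim != 1 or len(w) != len(i):
            raise ValidationError("spectrum wavenumbers/intensities must be equal-length 1-D")
        d = np.diff(w)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("spectrum wavenumbers must be strictly monotonic")

    def __len__(self) -> int:
        return len(self.wavenumbers)


@dataclass(frozen=True)
class FrequencyImage:
    """A single-frequency SRS image, optionally off-resonance subtracted."""

    image: np.ndarray
    center_wavenumber: float
    off_resonance_wavenumber: float | None = None

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        object.__setattr__(self, "image", img)
        if img.ndim != 2:
            raise ValidationError("frequency image must be 2-D")
        if self.off_resonance_wavenumber is not None and np.any(img < 0):
            raise ValidationError("off-resonance-subtracted image must be clipped at 0")


@dataclass(frozen=True)
class SegmentLabelImage:
    """Integer label per pixel (0 = unassigned) with segment names and colors."""

    labels: np.ndarray
    names: dict[int, str]
    colors: dict[int, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            labels = labels.astype(np.int32)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 2:
            raise ValidationError("label image must be 2-D")
        present = set(int(v) for v in np.unique(labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} have no segment name")
        declared = sorted(self.names)
        if declared and declared != list(range(1, len(declared) + 1)):
            raise ValidationError(f"labels must be dense 1..K, got {declared}")

    @property
    def n_segments(self) -> int:
        return len(self.names)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_stack(stack: HyperStack, stack_path: str | Path, axis_path: str | Path) -> None:
    """Write a stack as a multi-page grayscale TIFF plus a JSON axis sidecar.

    Integer data round-trips bit-exactly; float data is stored as float32.
    """
    arr = stack.intensities
    if np.issubdtype(arr.dtype, np.integer):
        pages = arr.astype(np.uint16) if arr.dtype != np.uint16 else arr
    else:
        pages = arr.astype(np.float32)
    # pages axis first for multi-page TIFF
    tifffile.imwrite(str(stack_path), np.moveaxis(pages, 2, 0), photometric="minisblack")
    sidecar = {
        "wavenumbers": [float(v) for v in stack.axis.values],
        "window_ids": [int(w) for w in stack.axis.window_ids],
        "step_nm": stack.axis.step_nm,
    }
    Path(axis_path).write_text(json.dumps(sidecar, indent=1))


def read_stack(stack_path: str | Path, axis_path: str | Path) -> HyperStack:
    """Read a multi-page TIFF stack and its JSON axis sidecar."""
    pages = tifffile.imread(str(stack_path))
    if pages.ndim == 2:
        pages = pages[None, :, :]
    try:
        meta = json.loads(Path(axis_path).read_text())
        wavenumbers = meta["wavenumbers"]
        window_ids = meta["window_ids"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise FormatError(f"axis sidecar {axis_path} is malformed: {exc}") from exc
    if len(wavenumbers) != pages.shape[0]:
        raise FormatError(
            f"TIFF has {pages.shape[0]} pages but axis lists {len(wavenumbers)} wavenumbers"
        )
    axis = WavenumberAxis(
        values=np.asarray(wavenumbers, dtype=float),
        window_ids=np.asarray(window_ids, dtype=int),
        step_nm=meta.get("step_nm"),
    )
    return HyperStack(intensities=np.moveaxis(pages, 0, 2), axis=axis)


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": spectrum.wavenumbers, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    if not {"wavenumber_cm1", "intensity"} <= set(df.columns):
        raise FormatError(
            f"{path}: expected columns wavenumber_cm1, intensity; got {list(df.columns)}"
        )
    return Spectrum(df["wavenumber_cm1"].to_numpy(), df["intensity"].to_numpy())


def write_label_image(labels: SegmentLabelImage, tiff_path: str | Path, json_path: str | Path) -> None:
    tifffile.imwrite(str(tiff_path), labels.labels.astype(np.uint16), photometric="minisblack")
    meta = {
        "names": {str(k): v for k, v in labels.names.items()},
        "colors": {str(k): list(v) for k, v in labels.colors.items()},
    }
    Path(json_path).write_text(json.dumps(meta, indent=1))


def read_label_image(tiff_path: str | Path, json_path: str | Path) -> SegmentLabelImage:
    arr = tifffile.imread(str(tiff_path)).astype(np.int32)
    meta = json.loads(Path(json_path).read_text())
    return SegmentLabelImage(
        labels=arr,
        names={int(k): v for k, v in meta["names"].items()},
        colors={int(k): tuple(v) for k, v in meta.get("colors", {}).items()},
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def pump_step_to_wavenumber_step(step_nm: float, pump_nm: float) -> float:
    """First-order Raman-shift increment for a small pump-wavelength step.

    d(nu~)/d(lambda) = -1/lambda^2 in consistent units, so a pump step of
    ``step_nm`` at wavelength ``pump_nm`` shifts the Raman axis by
    ``1e7 * step_nm / pump_nm**2`` cm^-1. A 0.4 nm step near 756 nm gives
    the ~7 cm^-1 frame spacing typical of hyperspectral SRS scans.
    """
    if pump_nm <= 0:
        raise DomainError(f"pump wavelength must be positive, got {pump_nm}")
    if step_nm < 0:
        raise DomainError(f"tuning step must be non-negative, got {step_nm}")
    return 1.0e7 * step_nm / pump_nm**2


def extract_frequency_image(
    stack: HyperStack,
    center: float,
    off_resonance: float | None = None,
) -> FrequencyImage:
    """Extract the frame nearest ``center``; optionally subtract the frame
    nearest ``off_resonance`` pixelwise, clipping negatives to 0.

    Off-resonance subtraction removes the non-Raman background: an image at
    a band-free frequency (e.g. 2400 cm^-1) contains only background, so the
    difference isolates the resonant signal. SRS intensity is physically
    non-negative, hence the clip.
    """
    img = np.asarray(stack.intensities[:, :, stack.nearest_frame_index(center)], dtype=float)
    if off_resonance is None:
        return FrequencyImage(image=img, center_wavenumber=center)
    off = np.asarray(
        stack.intensities[:, :, stack.nearest_frame_index(off_resonance)], dtype=float
    )
    return FrequencyImage(
        image=np.clip(img - off, 0.0, None),
        center_wavenumber=center,
        off_resonance_wavenumber=off_resonance,
    )
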