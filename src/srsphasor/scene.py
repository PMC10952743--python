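"""Synthetic hyperspectral SRS scenes with pixel-level ground truth.

The generator emulates a triplex bioorthogonal labelling experiment on a
single adherent cell: a metallacarborane (B-H stretch, 2480-2650 cm^-1)
distributed through the cytoplasm and weakly in the nucleus, a deuterated
fatty acid (CD2, 2102 cm^-1) and a bis-alkyne AM-ester (C#C, 2220 cm^-1)
co-localized in a subset of lipid droplets, and AM-ester-only pockets in
the cytoplasm — on top of six label-free compartments distinguished by
their C-H-region spectra (nucleus, nucleolus, cytoplasm, lipid droplets,
LD periphery, cell boundary). Scanning follows the three-window plan
3050-2800 (40 frames), 2650-2450 (35) and 2250-2000 cm^-1 (40), ~7 cm^-1
per frame, frames emitted in acquisition order (descending wavenumber).

Every pixel's analytic spectrum is a weighted sum of packaged reference
spectra; noise is Poisson-scaled shot noise plus additive Gaussian read
noise over an optional constant offset. Geometry, spectra and noise are all
deterministic given the scene seed, and the class masks are the test oracle
for segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.morphology import dilation, disk, erosion

from .errors import DomainError, PlacementError, ValidationError
from .hyperstack import HyperStack, Spectrum, WavenumberAxis
from .spectra import ReferenceSpectrum, builtin_references, evaluate_reference

__all__ = [
    "ScanPlan",
    "NoiseModel",
    "SceneSpec",
    "GroundTruth",
    "DEFAULT_SCAN_PLAN",
    "SILENT_WINDOWS",
    "build_scene",
    "render_stack",
    "scene_presets",
    "analytic_class_spectra",
    "probe_truth_masks",
]

#: Probe components recognised when deriving probe-level truth masks.
_PROBE_COMPONENTS = (
    "metallacarborane",
    "stearic_d35",
    "butadiyne_am_ester",
    "butadiyne_imidazole",
    "cosan_d2",
)


@dataclass(frozen=True)
class ScanPlan:
    """Acquisition windows as (lo, hi, frame_count) in cm^-1.

    Frames are rendered in acquisition order: descending wavenumber within
    each window (the pump laser tunes from short to long wavelength).
    """

    windows: tuple[tuple[float, float, int], ...]
    step_nm: float = 0.4

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "windows", tuple((float(a), float(b), int(n)) for a, b, n in self.windows)
        )
        for lo, hi, n in self.windows:
            if not lo < hi:
                raise ValidationError(f"window must have lo < hi, got ({lo}, {hi})")
            if n < 2:
                raise ValidationError(f"window ({lo}, {hi}) needs >= 2 frames, got {n}")
        spans = sorted((lo, hi) for lo, hi, _ in self.windows)
        for (l1, h1), (l2, h2) in zip(spans, spans[1:]):
            if h1 >= l2:
                raise ValidationError(f"windows overlap: ({l1},{h1}) and ({l2},{h2})")

    @property
    def n_frames(self) -> int:
        return sum(n for _, _, n in self.windows)

    def axis(self, window_index: int) -> np.ndarray:
        lo, hi, n = self.windows[window_index]
        return np.linspace(hi, lo, n)  # acquisition order: descending


#: The triplex scan plan: C-H window plus the two cell-silent windows.
DEFAULT_SCAN_PLAN = ScanPlan(windows=((2800.0, 3050.0, 40), (2450.0, 2650.0, 35), (2000.0, 2250.0, 40)))

#: Indices (into DEFAULT_SCAN_PLAN.windows) of the cell-silent windows.
SILENT_WINDOWS = (1, 2)


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise. ``None`` fields are resolved against the scene:

    - gaussian_sd -> 2% of the peak analytic compartment amplitude,
    - poisson_scale -> chosen so the shot-noise SNR at the brightest band
      is ~20 (scale = 400 / peak amplitude).

    ``offset`` is a constant non-resonant background added before the read
    noise. ``poisson_scale = 0`` and ``gaussian_sd = 0`` disable noise.
    """

    gaussian_sd: float | None = None
    poisson_scale: float | None = None
    offset: float = 0.0

    @classmethod
    def disabled(cls) -> "NoiseModel":
        return cls(gaussian_sd=0.0, poisson_scale=0.0, offset=0.0)


@dataclass(frozen=True)
class SceneSpec:
    """Geometric and spectral ground truth for one synthetic cell."""

    shape: tuple[int, int] = (256, 256)
    cell_center: tuple[float, float] = (128.0, 128.0)
    cell_axes: tuple[float, float] = (105.0, 88.0)
    nucleus_center: tuple[float, float] = (112.0, 118.0)
    nucleus_axes: tuple[float, float] = (42.0, 34.0)
    nucleolus_count: int = 4
    nucleolus_radius: int = 8
    ld_count: int = 10
    labeled_ld_count: int = 0
    ld_radius: int = 5
    ld_periphery_width: int = 3
    boundary_width: int = 4
    probe_pockets: tuple[tuple[str, int, int, str], ...] = ()
    #: class name -> {reference component -> weight}
    class_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=NoiseModel)
    scan_plan: ScanPlan = DEFAULT_SCAN_PLAN
    seed: int = 0

    def __post_init__(self) -> None:
        for cname, weights in self.class_weights.items():
            for comp, w in weights.items():
                if w < 0:
                    raise ValidationError(f"{cname}: negative weight for {comp}")

    def with_seed(self, seed: int) -> "SceneSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class GroundTruth:
    """Disjoint boolean class masks, aligned with SceneSpec.class_weights."""

    masks: dict[str, np.ndarray]

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(self.masks)

    def nonempty_classes(self) -> tuple[str, ...]:
        return tuple(n for n, m in self.masks.items() if m.any())

    def as_label_image(self) -> np.ndarray:
        first = next(iter(self.masks.values()))
        labels = np.zeros(first.shape, dtype=np.int32)
        for i, mask in enumerate(self.masks.values(), start=1):
            labels[mask] = i
        return labels


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _place_disks(
    rng: np.random.Generator,
    allowed: np.ndarray,
    count: int,
    radius: int,
    placed: list[tuple[int, int, int]],
    gap: int,
    what: str,
    max_tries: int = 1000,
) -> list[tuple[int, int]]:
    """Rejection-sample non-overlapping disk centers inside ``allowed``."""
    coords = np.argwhere(allowed)
    if count > 0 and len(coords) == 0:
        raise PlacementError(f"no admissible pixels for {what}")
    centers: list[tuple[int, int]] = []
    for _ in range(count):
        for _try in range(max_tries):
            r, c = coords[rng.integers(len(coords))]
            ok = all(
                (r - pr) ** 2 + (c - pc) ** 2 > (radius + prad + gap) ** 2
                for pr, pc, prad in placed
            )
            if ok:
                centers.append((int(r), int(c)))
                placed.append((int(r), int(c), radius))
                break
        else:
            raise PlacementError(
                f"could not place {what} #{len(centers) + 1} after {max_tries} tries"
            )
    return centers


def build_scene(spec: SceneSpec) -> GroundTruth:
    """Realise a SceneSpec's geometry into disjoint ground-truth class masks.

    Nucleoli, lipid droplets and probe pockets are placed uniformly at
    random (seeded) inside their parent compartments without overlap,
    bounded by a retry budget; the LD periphery and cell boundary are
    morphological dilation/erosion bands.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    cell = _ellipse_mask(shape, spec.cell_center, spec.cell_axes)
    nucleus = _ellipse_mask(shape, spec.nucleus_center, spec.nucleus_axes)
    if not (nucleus <= cell).all():
        raise ValidationError("nucleus must lie inside the cell")
    boundary = cell & ~erosion(cell, disk(spec.boundary_width))
    cyto_region = cell & ~nucleus & ~boundary

    placed: list[tuple[int, int, int]] = []

    # nucleoli inside the nucleus
    nucleolus_allowed = erosion(nucleus, disk(spec.nucleolus_radius + 1))
    nucleolus_centers = _place_disks(
        rng, nucleolus_allowed, spec.nucleolus_count, spec.nucleolus_radius, placed, 2, "nucleolus"
    )

    # lipid droplets (plain then labelled) deep enough in the cytoplasm that
    # their periphery annulus stays cytoplasmic
    ld_margin = spec.ld_radius + spec.ld_periphery_width + 1
    ld_allowed = erosion(cyto_region, disk(ld_margin))
    ld_centers = _place_disks(
        rng, ld_allowed, spec.ld_count, spec.ld_radius, placed, spec.ld_periphery_width + 1, "lipid droplet"
    )
    labeled_centers = _place_disks(
        rng, ld_allowed, spec.labeled_ld_count, spec.ld_radius, placed,
        spec.ld_periphery_width + 1, "labelled lipid droplet",
    )

    # probe pockets in their parent compartment
    pocket_masks: dict[str, np.ndarray] = {}
    for pname, count, radius, parent in spec.probe_pockets:
        if parent == "cytoplasm":
            region = cyto_region
        elif parent == "cell":
            region = cell & ~boundary
        else:
            raise ValidationError(f"unknown pocket parent {parent!r}")
        allowed = erosion(region, disk(radius + 1))
        centers = _place_disks(rng, allowed, count, radius, placed, 2, f"{pname} pocket")
        m = np.zeros(shape, dtype=bool)
        for ctr in centers:
            m |= _disk_mask(shape, ctr, radius)
        pocket_masks[pname] = m

    def union_disks(centers, radius):
        m = np.zeros(shape, dtype=bool)
        for ctr in centers:
            m |= _disk_mask(shape, ctr, radius)
        return m

    nucleoli = union_disks(nucleolus_centers, spec.nucleolus_radius) & nucleus
    ld_plain = union_disks(ld_centers, spec.ld_radius)
    ld_labeled = union_disks(labeled_centers, spec.ld_radius)
    ld_all = ld_plain | ld_labeled
    periphery = (
        dilation(ld_all, disk(spec.ld_periphery_width)) & ~ld_all & cyto_region
        if ld_all.any()
        else np.zeros(shape, dtype=bool)
    )

    taken = np.zeros(shape, dtype=bool)
    masks: dict[str, np.ndarray] = {}

    def claim(name: str, mask: np.ndarray) -> None:
        nonlocal taken
        m = mask & ~taken
        masks[name] = m
        taken = taken | m

    # priority order keeps the small structures intact
    claim("nucleolus", nucleoli)
    claim("lipid_droplets", ld_plain)
    if spec.labeled_ld_count or "stearic_am_lds" in spec.class_weights:
        claim("stearic_am_lds", ld_labeled)
    claim("ld_periphery", periphery)
    for pname in pocket_masks:
        claim(pname, pocket_masks[pname] & ~nucleus)
        if (pname, "cell") in [(p[0], p[3]) for p in spec.probe_pockets]:
            # pan-cellular pockets may extend into the nucleus
            claim_extra = pocket_masks[pname] & nucleus & ~taken
            masks[pname] = masks[pname] | claim_extra
            taken = taken | claim_extra
    claim("nucleus", nucleus)
    claim("cell_boundary", boundary)
    claim("cytoplasm", cell)

    # order masks to match class_weights where given
    if spec.class_weights:
        unknown = set(spec.class_weights) - set(masks)
        if unknown:
            raise ValidationError(f"class_weights name unknown classes: {sorted(unknown)}")
        ordered = {n: masks[n] for n in spec.class_weights}
        for n, m in masks.items():
            if n not in ordered:
                ordered[n] = m
        masks = ordered
    return GroundTruth(masks=masks)


def analytic_class_spectra(
    spec: SceneSpec,
    plan: ScanPlan | None = None,
    references: dict[str, ReferenceSpectrum] | None = None,
) -> dict[str, Spectrum]:
    """Noise-free per-class spectra on the concatenated acquisition axis."""
    plan = plan or spec.scan_plan
    refs = references or builtin_references()
    axis = np.concatenate([plan.axis(i) for i in range(len(plan.windows))])
    out: dict[str, Spectrum] = {}
    for cname, weights in spec.class_weights.items():
        total = np.zeros_like(axis)
        for comp, w in weights.items():
            total += w * evaluate_reference(refs[comp], axis).intensities
        # windows are listed high-to-low and scanned descending, so the
        # concatenated acquisition axis is globally strictly descending
        out[cname] = Spectrum(wavenumbers=axis.copy(), intensities=total)
    return out


def _resolve_noise(spec: SceneSpec, class_spectra: dict[str, Spectrum]) -> NoiseModel:
    peak = max(
        (float(s.intensities.max()) for s in class_spectra.values()), default=1.0
    )
    gaussian_sd = spec.noise.gaussian_sd
    poisson_scale = spec.noise.poisson_scale
    if gaussian_sd is None:
        gaussian_sd = 0.02 * peak
    if poisson_scale is None:
        poisson_scale = 400.0 / peak if peak > 0 else 0.0
    return NoiseModel(gaussian_sd=gaussian_sd, poisson_scale=poisson_scale, offset=spec.noise.offset)


def render_stack(
    truth: GroundTruth,
    spec: SceneSpec,
    plan: ScanPlan | None = None,
) -> list[HyperStack]:
    """Render one HyperStack per acquisition window from ground truth.

    Each pixel's analytic spectrum is its class's weighted reference sum
    evaluated on the window axis; shot noise (Poisson with ``poisson_scale``
    counts per intensity unit), a constant offset and Gaussian read noise
    are then applied, and negatives are clipped (SRS intensities are
    physically non-negative).
    """
    plan = plan or spec.scan_plan
    refs = builtin_references()
    for lo, hi, _ in plan.windows:
        if lo < 200.0 or hi > 3100.0:
            raise ValidationError(f"window ({lo}, {hi}) outside reference range 200-3100")
    class_spectra_full = analytic_class_spectra(spec, plan, refs)
    noise = _resolve_noise(spec, class_spectra_full)
    rng = np.random.default_rng(spec.seed + 1)
    stacks: list[HyperStack] = []
    frame_start = 0
    for widx, (lo, hi, n) in enumerate(plan.windows):
        axis_vals = plan.axis(widx)
        cube = np.zeros(spec.shape + (n,), dtype=float)
        for cname, mask in truth.masks.items():
            if cname not in spec.class_weights or not mask.any():
                continue
            cube[mask] = class_spectra_full[cname].intensities[frame_start : frame_start + n]
        frame_start += n
        if noise.poisson_scale and noise.poisson_scale > 0:
            cube = rng.poisson(cube * noise.poisson_scale) / noise.poisson_scale
        cube = cube + noise.offset
        if noise.gaussian_sd and noise.gaussian_sd > 0:
            cube = cube + rng.normal(0.0, noise.gaussian_sd, size=cube.shape)
        cube = np.clip(cube, 0.0, None)
        axis = WavenumberAxis(
            values=axis_vals,
            window_ids=np.full(n, widx, dtype=int),
            step_nm=plan.step_nm,
        )
        stacks.append(HyperStack(intensities=cube, axis=axis))
    return stacks


def probe_truth_masks(spec: SceneSpec, truth: GroundTruth) -> dict[str, np.ndarray]:
    """Probe-level ground truth for silent-region unmixing.

    Classes are grouped by which probe components they carry: the B-H
    channel (metallacarborane-bearing classes), the co-localized
    C-D + C#C channel (deuterated fatty acid present) and the
    C#C-only channel (bis-alkyne without the fatty acid).
    """
    shape = next(iter(truth.masks.values())).shape
    bh = np.zeros(shape, dtype=bool)
    colocal = np.zeros(shape, dtype=bool)
    alkyne_only = np.zeros(shape, dtype=bool)
    for cname, weights in spec.class_weights.items():
        has = {p: weights.get(p, 0.0) > 0 for p in _PROBE_COMPONENTS}
        mask = truth.masks[cname]
        if has["metallacarborane"] or has["cosan_d2"]:
            bh |= mask
        if has["stearic_d35"] and (has["butadiyne_am_ester"] or has["butadiyne_imidazole"]):
            colocal |= mask
        elif has["butadiyne_am_ester"] or has["butadiyne_imidazole"]:
            alkyne_only |= mask
    out = {}
    if bh.any():
        out["probe_bh"] = bh
    if colocal.any():
        out["probe_cd_alkyne"] = colocal
    if alkyne_only.any():
        out["probe_alkyne_only"] = alkyne_only
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# Compartment C-H weight choices are plausibility values (relative SRS
# amplitudes of compartment spectra are not tabulated anywhere); they are
# chosen so the six label-free classes differ in spectral *shape* (the
# phasor ignores brightness) and the probe weights follow the described
# localization: metallacarborane through the cytoplasm with ~0.3x weaker
# nuclear association, fatty acid + AM-ester in labelled droplets,
# AM-ester-only pockets elsewhere.
_TRIPLEX_WEIGHTS: dict[str, dict[str, float]] = {
    "nucleus": {"protein_ch3": 1.0, "lipid_ch2": 0.15, "metallacarborane": 0.04},
    "nucleolus": {"protein_ch3": 2.4, "lipid_ch2": 0.05, "metallacarborane": 0.03},
    "cytoplasm": {"protein_ch3": 0.75, "lipid_ch2": 0.45, "metallacarborane": 0.13},
    "lipid_droplets": {"protein_ch3": 0.15, "lipid_ch2": 2.2},
    "ld_periphery": {"protein_ch3": 0.55, "lipid_ch2": 1.2, "metallacarborane": 0.10},
    "cell_boundary": {"protein_ch3": 0.70, "lipid_ch2": 0.80, "metallacarborane": 0.06},
    "crsan_pockets": {"protein_ch3": 0.75, "lipid_ch2": 0.45, "metallacarborane": 0.50},
    "stearic_am_lds": {
        "protein_ch3": 0.15,
        "lipid_ch2": 2.0,
        "stearic_d35": 1.2,
        "butadiyne_am_ester": 0.06,
    },
    "am_pockets": {"protein_ch3": 0.75, "lipid_ch2": 0.40, "butadiyne_am_ester": 0.12},
}

_SINGLEPLEX_WEIGHTS: dict[str, dict[str, float]] = {
    "nucleus": {"protein_ch3": 1.0, "lipid_ch2": 0.15},
    "nucleolus": {"protein_ch3": 2.4, "lipid_ch2": 0.05, "metallacarborane": 0.25},
    "cytoplasm": {"protein_ch3": 0.75, "lipid_ch2": 0.45, "metallacarborane": 0.08},
    "lipid_droplets": {"protein_ch3": 0.15, "lipid_ch2": 2.2},
    "ld_periphery": {"protein_ch3": 0.55, "lipid_ch2": 1.2, "metallacarborane": 0.05},
    "cell_boundary": {"protein_ch3": 0.70, "lipid_ch2": 0.80},
    "fesan_pockets": {"protein_ch3": 0.75, "lipid_ch2": 0.45, "metallacarborane": 0.40},
}

_IMIDAZOLE_WEIGHTS: dict[str, dict[str, float]] = {
    "nucleus": {"protein_ch3": 1.0, "lipid_ch2": 0.15, "metallacarborane": 0.04, "butadiyne_imidazole": 0.03},
    "nucleolus": {"protein_ch3": 2.4, "lipid_ch2": 0.05, "metallacarborane": 0.03, "butadiyne_imidazole": 0.03},
    "cytoplasm": {"protein_ch3": 0.75, "lipid_ch2": 0.45, "metallacarborane": 0.13, "butadiyne_imidazole": 0.04},
    "lipid_droplets": {"protein_ch3": 0.15, "lipid_ch2": 2.2},
    "ld_periphery": {"protein_ch3": 0.55, "lipid_ch2": 1.2, "metallacarborane": 0.10},
    "cell_boundary": {"protein_ch3": 0.70, "lipid_ch2": 0.80, "metallacarborane": 0.06},
    "crsan_pockets": {"protein_ch3": 0.75, "lipid_ch2": 0.45, "metallacarborane": 0.50},
    "stearic_am_lds": {
        "protein_ch3": 0.15,
        "lipid_ch2": 2.0,
        "stearic_d35": 1.2,
        "butadiyne_imidazole": 0.05,
    },
    "am_pockets": {"protein_ch3": 0.75, "lipid_ch2": 0.40, "butadiyne_imidazole": 0.10},
}


def scene_presets() -> dict[str, SceneSpec]:
    """Named scene presets mirroring the single-plex and triplex experiments.

    - ``triplex_crsan``: the headline 9-class scene (six compartments +
      metallacarborane channel + co-localized fatty-acid/alkyne droplets +
      alkyne-only pockets) over the three-window 115-frame plan.
    - ``singleplex_fesan``: 7 classes (six compartments + probe pockets,
      probe also in the nucleolus) over the C-H and B-H windows only.
    - ``triplex_imidazole``: as triplex but with the pan-cellular imidazole
      bis-alkyne, which also enters the nuclei.
    """
    triplex = SceneSpec(
        labeled_ld_count=10,
        probe_pockets=(("crsan_pockets", 6, 10, "cytoplasm"), ("am_pockets", 5, 9, "cytoplasm")),
        class_weights=_TRIPLEX_WEIGHTS,
        scan_plan=DEFAULT_SCAN_PLAN,
    )
    singleplex = SceneSpec(
        labeled_ld_count=0,
        probe_pockets=(("fesan_pockets", 6, 10, "cytoplasm"),),
        class_weights=_SINGLEPLEX_WEIGHTS,
        scan_plan=ScanPlan(windows=((2800.0, 3050.0, 40), (2450.0, 2650.0, 35))),
    )
    imidazole = SceneSpec(
        labeled_ld_count=10,
        probe_pockets=(("crsan_pockets", 6, 10, "cytoplasm"), ("am_pockets", 5, 9, "cell")),
        class_weights=_IMIDAZOLE_WEIGHTS,
        scan_plan=DEFAULT_SCAN_PLAN,
    )
    return {
        "triplex_crsan": triplex,
        "singleplex_fesan": singleplex,
        "triplex_imidazole": imidazole,
    }


def get_preset(name: str) -> SceneSpec:
    presets = scene_presets()
    if name not in presets:
        raise DomainError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]
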