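import numpy as np
import pytest

from srsphasor.hyperstack import HyperStack, WavenumberAxis
from srsphasor.scene import NoiseModel, ScanPlan, SceneSpec, build_scene, render_stack

# compact triplex-like scene for fast unit tests; same class structure as
# the full preset, scaled to 64x64
SMALL_WEIGHTS = {
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

SMALL_PLAN = ScanPlan(windows=((2800.0, 3050.0, 12), (2450.0, 2650.0, 10), (2000.0, 2250.0, 12)))


def small_scene_spec(seed: int = 0, noise: NoiseModel | None = None) -> SceneSpec:
    return SceneSpec(
        shape=(64, 64),
        cell_center=(32.0, 32.0),
        cell_axes=(27.0, 23.0),
        nucleus_center=(27.0, 29.0),
        nucleus_axes=(11.0, 9.0),
        nucleolus_count=1,
        nucleolus_radius=3,
        ld_count=2,
        labeled_ld_count=2,
        ld_radius=2,
        ld_periphery_width=1,
        boundary_width=2,
        probe_pockets=(("crsan_pockets", 2, 3, "cytoplasm"), ("am_pockets", 2, 3, "cytoplasm")),
        class_weights=SMALL_WEIGHTS,
        noise=noise or NoiseModel(),
        scan_plan=SMALL_PLAN,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_spec() -> SceneSpec:
    return small_scene_spec(seed=0)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return build_scene(small_spec)


@pytest.fixture(scope="session")
def small_stacks(small_spec, small_truth):
    return render_stack(small_truth, small_spec)


@pytest.fixture(scope="session")
def noiseless_spec() -> SceneSpec:
    return small_scene_spec(seed=0, noise=NoiseModel.disabled())


@pytest.fixture(scope="session")
def noiseless_stacks(noiseless_spec):
    truth = build_scene(noiseless_spec)
    return truth, render_stack(truth, noiseless_spec)


def make_stack(intensities: np.ndarray, wavenumbers=None, window_ids=None) -> HyperStack:
    """Stack from a raw array with a simple ascending axis."""
    n = intensities.shape[2]
    if wavenumbers is None:
        wavenumbers = 2000.0 + 7.0 * np.arange(n)
    if window_ids is None:
        window_ids = np.zeros(n, dtype=int)
    return HyperStack(
        intensities=intensities,
        axis=WavenumberAxis(values=np.asarray(wavenumbers, dtype=float),
                            window_ids=np.asarray(window_ids, dtype=int)),
    )
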