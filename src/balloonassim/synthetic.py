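"""Synthetic inputs with exactly known ground truth.

Everything the pipeline consumes can be generated here: block-design
stimulus trains, single- and two-region noisy BOLD datasets (fMRI-like
TR = 2 s, 200 scans, 20 s on/off blocks by default), and high-resolution
vessel phantoms whose per-functional-voxel vessel fractions are known by
exact subvoxel counting.  Noise is i.i.d. Gaussian with a standard deviation
set from the requested SNR (peak noiseless amplitude over noise sd); every
generator is reproducible from its seed, and scenarios serialize to plain
dicts/YAML so a dataset can be regenerated bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dcm import DCMConnectivity, DCMModel, DCMSimulation, simulate_dcm
from .model import (DEFAULT_PARAMS, BoldSimulation, HemodynamicParams,
                    StimulusTrain, simulate_bold)
from .v0map import HighResVolume

__all__ = [
    "SyntheticScenario",
    "TwoRegionScenario",
    "VesselPhantomSpec",
    "VesselSegment",
    "make_block_design",
    "make_single_region_dataset",
    "make_two_region_dataset",
    "make_vessel_phantom",
    "default_single_region_scenario",
    "small_signal_scenario",
    "default_two_region_scenario",
    "default_phantom_spec",
]


def make_block_design(n_blocks: int, block_s: float = 20.0,
                      rest_s: float = 20.0, dt: float = 2.0) -> StimulusTrain:
    """Alternating rest/stimulus boxcar, starting (and ending) with rest."""
    if block_s <= 0 or rest_s <= 0:
        raise ValueError("block_s and rest_s must be positive")
    onsets = tuple(rest_s + k * (block_s + rest_s) for k in range(n_blocks))
    return StimulusTrain(onsets=onsets, durations=(block_s,) * n_blocks,
                         amplitude=1.0, sampling_dt=dt)


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth specification of a single-region acquisition."""

    name: str = "single_region_v1"
    params: HemodynamicParams = field(
        default_factory=lambda: DEFAULT_PARAMS.with_v0(0.1))
    n_blocks: int = 9
    block_s: float = 20.0
    rest_s: float = 20.0
    tr: float = 2.0
    n_scans: int = 200
    snr: float = 10.0
    amplitude: float = 0.3
    seed: int = 0

    def stimulus(self) -> StimulusTrain:
        base = make_block_design(self.n_blocks, self.block_s, self.rest_s,
                                 self.tr)
        return StimulusTrain(base.onsets, base.durations,
                             amplitude=self.amplitude, sampling_dt=self.tr)

    def sample_times(self) -> np.ndarray:
        return self.tr * np.arange(self.n_scans)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "name": self.name,
            "params": {k: getattr(p, k) for k in
                       ("epsilon", "tau_s", "tau_f", "tau_0", "E0", "alpha", "V0")},
            "n_blocks": self.n_blocks, "block_s": self.block_s,
            "rest_s": self.rest_s, "tr": self.tr, "n_scans": self.n_scans,
            "snr": self.snr, "amplitude": self.amplitude, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        d = dict(d)
        d["params"] = HemodynamicParams(**d["params"])
        return cls(**d)


def make_single_region_dataset(scenario: SyntheticScenario) -> BoldSimulation:
    """Simulate the scenario; noise sd = (peak noiseless amplitude) / SNR."""
    stim = scenario.stimulus()
    times = scenario.sample_times()
    clean = simulate_bold(scenario.params, stim, times, noise_sd=0.0)
    peak = float(np.max(np.abs(clean.bold_noiseless)))
    noise_sd = peak / scenario.snr if scenario.snr > 0 else 0.0
    rng = np.random.default_rng(scenario.seed)
    noisy = clean.bold_noiseless + rng.normal(0.0, noise_sd, size=times.size)
    return BoldSimulation(times=times, bold_noiseless=clean.bold_noiseless,
                          bold_noisy=noisy, states=clean.states,
                          params=scenario.params, noise_sd=noise_sd,
                          seed=scenario.seed)


@dataclass(frozen=True)
class TwoRegionScenario:
    """Ground truth of a two-region (DCM) acquisition.

    Region 1 emulates a vein-dominated locus (V0 = 0.1), region 2 vessel-free
    tissue (V0 = 0.02); both driven by the same block squarewave.
    """

    name: str = "two_region_v1_v5"
    model: DCMModel = field(default_factory=DCMModel)
    n_blocks: int = 9
    block_s: float = 20.0
    rest_s: float = 20.0
    tr: float = 2.0
    n_scans: int = 200
    snr: float = 10.0
    seed: int = 0

    def stimulus(self) -> StimulusTrain:
        return make_block_design(self.n_blocks, self.block_s, self.rest_s,
                                 self.tr)

    def sample_times(self) -> np.ndarray:
        return self.tr * np.arange(self.n_scans)

    def to_dict(self) -> dict:
        c = self.model.connectivity
        return {
            "name": self.name,
            "connectivity": {k: getattr(c, k) for k in
                             ("a11", "a22", "a12", "a21", "c1", "c2")},
            "region1": SyntheticScenario(params=self.model.region1).to_dict()["params"],
            "region2": SyntheticScenario(params=self.model.region2).to_dict()["params"],
            "n_blocks": self.n_blocks, "block_s": self.block_s,
            "rest_s": self.rest_s, "tr": self.tr, "n_scans": self.n_scans,
            "snr": self.snr, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoRegionScenario":
        d = dict(d)
        model = DCMModel(connectivity=DCMConnectivity(**d.pop("connectivity")),
                         region1=HemodynamicParams(**d.pop("region1")),
                         region2=HemodynamicParams(**d.pop("region2")))
        return cls(model=model, **d)


def make_two_region_dataset(scenario: TwoRegionScenario) -> DCMSimulation:
    """Simulate both regions; per-region noise sd = that region's peak / SNR."""
    stim = scenario.stimulus()
    times = scenario.sample_times()
    clean = simulate_dcm(scenario.model, stim, times, noise_sd=(0.0, 0.0))
    peaks = np.max(np.abs(clean.bold_noiseless), axis=0)
    noise_sd = tuple(p / scenario.snr if scenario.snr > 0 else 0.0
                     for p in peaks)
    rng = np.random.default_rng(scenario.seed)
    noisy = clean.bold_noiseless.copy()
    for r in range(2):
        noisy[:, r] += rng.normal(0.0, noise_sd[r], size=times.size)
    return DCMSimulation(times=times, bold_noiseless=clean.bold_noiseless,
                         bold_noisy=noisy, states=clean.states,
                         model=scenario.model, noise_sd=noise_sd,
                         seed=scenario.seed)


@dataclass(frozen=True)
class VesselSegment:
    """Straight cylinder in subvoxel coordinates (radius in subvoxels).

    ``intensity`` overrides the phantom's default vessel intensity, allowing
    graded vessel brightness (as in real angiography, where signal depends
    on flow velocity).
    """

    start: tuple
    end: tuple
    radius: float = 0.0
    intensity: float | None = None


@dataclass(frozen=True)
class VesselPhantomSpec:
    """Specification of a high-resolution vessel phantom."""

    grid_shape: tuple = (8, 8, 4)
    factors: tuple = (4, 4, 4)
    segments: tuple = ()
    background_intensity: float = 100.0
    vessel_intensity: float = 1000.0
    n_noise_voxels: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vessel_intensity <= self.background_intensity:
            raise ValueError("vessel intensity must exceed background")
        hi = self.highres_shape
        for seg in self.segments:
            for p in (seg.start, seg.end):
                if any(not 0 <= c <= s - 1 for c, s in zip(p, hi)):
                    raise ValueError(f"segment endpoint {p} outside {hi}")

    @property
    def highres_shape(self) -> tuple:
        return tuple(s * f for s, f in zip(self.grid_shape, self.factors))


@dataclass
class VesselPhantom:
    """Generated phantom plus its exact-count oracle."""

    volume: HighResVolume
    vessel_mask: np.ndarray          # vessel-only (no injected noise)
    fraction_table: np.ndarray       # exact per-functional-voxel fraction
    noise_voxels: list               # injected isolated supra-threshold voxels
    spec: VesselPhantomSpec


def _rasterize_segment(shape, seg: VesselSegment) -> np.ndarray:
    """Subvoxels whose integer center is within ``radius`` of the segment."""
    a = np.asarray(seg.start, dtype=float)
    b = np.asarray(seg.end, dtype=float)
    idx = np.indices(shape, dtype=float)
    pts = np.stack([idx[0], idx[1], idx[2]], axis=-1)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        t = np.zeros(shape)
    else:
        t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    dist = np.linalg.norm(pts - closest, axis=-1)
    return dist <= seg.radius + 1e-9


def make_vessel_phantom(spec: VesselPhantomSpec) -> VesselPhantom:
    """Rasterize vessel segments and inject isolated noise voxels.

    The fraction table is computed by exact integer counting of the vessel
    raster (before noise injection) and serves as the oracle for the
    calibration pipeline.  Injected noise voxels are guaranteed isolated:
    each is placed at Chebyshev distance >= 2 from every vessel voxel and
    from every other noise voxel, so thresholding plus the isolated-voxel
    rule removes exactly ``n_noise_voxels`` of them.
    """
    shape = spec.highres_shape
    vessel = np.zeros(shape, dtype=bool)
    intensities = np.full(shape, spec.background_intensity)
    for seg in spec.segments:
        raster = _rasterize_segment(shape, seg)
        if raster.sum() < 2:
            raise ValueError(
                "each segment must rasterize to >= 2 subvoxels (a 1-voxel "
                "segment would be removed as isolated noise)")
        vessel |= raster
        level = seg.intensity if seg.intensity is not None \
            else spec.vessel_intensity
        intensities[raster] = np.maximum(intensities[raster], level)

    nx, ny, nz = spec.grid_shape
    fx, fy, fz = spec.factors
    counts = vessel.reshape(nx, fx, ny, fy, nz, fz).sum(axis=(1, 3, 5))
    fraction = counts / (fx * fy * fz)
    rng = np.random.default_rng(spec.seed)
    noise_voxels: list = []
    if spec.n_noise_voxels > 0:
        from scipy import ndimage

        forbidden = ndimage.binary_dilation(vessel, np.ones((3, 3, 3)))
        attempts = 0
        while len(noise_voxels) < spec.n_noise_voxels:
            attempts += 1
            if attempts > 10000:
                raise RuntimeError(
                    "could not place isolated noise voxels; grid too crowded")
            cand = tuple(int(rng.integers(0, s)) for s in shape)
            if forbidden[cand]:
                continue
            if any(max(abs(c - d) for c, d in zip(cand, prev)) < 2
                   for prev in noise_voxels):
                continue
            noise_voxels.append(cand)
        for vox in noise_voxels:
            intensities[vox] = spec.vessel_intensity
    volume = HighResVolume(intensities=intensities.astype(float))
    return VesselPhantom(volume=volume, vessel_mask=vessel,
                         fraction_table=fraction, noise_voxels=noise_voxels,
                         spec=spec)


# ---------------------------------------------------------------------------
# Default study conditions

def offset_prior_params() -> HemodynamicParams:
    """A deliberately perturbed parameter prior for recovery studies.

    Initializing the filter at the generating parameters makes recovery
    trivial (zero noise keeps the estimate at the prior, which is already
    the truth), so bias-vs-noise studies start from this plausible but
    offset parameter set instead and must travel to the data.
    """
    return HemodynamicParams(epsilon=0.4, tau_s=1.25, tau_f=2.0, tau_0=1.25,
                             E0=0.45)


def default_single_region_scenario(seed: int = 0) -> SyntheticScenario:
    """Vein-dominated single region: truth V0 = 0.1, TR 2 s, 200 scans, SNR 10."""
    return SyntheticScenario(seed=seed)


def small_signal_scenario(seed: int = 0) -> SyntheticScenario:
    """Low-amplitude stimulus variant for first-order eps/V0 trade-off checks.

    The input level keeps flow/volume/dHb excursions to a few percent, the
    regime in which the BOLD response is linear in the product eps*V0 to
    first order and the two are individually unidentifiable.
    """
    return SyntheticScenario(name="single_region_small_signal",
                             amplitude=0.05, seed=seed)


def default_two_region_scenario(seed: int = 0) -> TwoRegionScenario:
    """Two-region truth: region 1 V0 = 0.1 (large vein), region 2 V0 = 0.02."""
    return TwoRegionScenario(seed=seed)


def default_phantom_spec(seed: int = 0, n_noise_voxels: int = 5) -> VesselPhantomSpec:
    """A seeded random phantom: 2-3 straight vessels through an 8x8x4 grid.

    Segment endpoints, radii (0-2 subvoxels) and graded vessel intensities
    (400-1000 over a background of 100) are drawn reproducibly from the seed
    on the 32x32x16 subvoxel lattice.  A segmentation threshold of 250 keeps
    every vessel; thresholds inside 400-1000 progressively drop the dimmer
    ones, which is what makes threshold-monotonicity checks informative.
    """
    rng = np.random.default_rng(seed)
    grid_shape, factors = (8, 8, 4), (4, 4, 4)
    hi = tuple(s * f for s, f in zip(grid_shape, factors))
    segments = []
    for _ in range(int(rng.integers(2, 4))):
        axis = int(rng.integers(0, 3))
        start = [int(rng.integers(2, s - 2)) for s in hi]
        end = list(start)
        start[axis] = int(rng.integers(0, hi[axis] // 3))
        end[axis] = int(rng.integers(2 * hi[axis] // 3, hi[axis]))
        segments.append(VesselSegment(start=tuple(start), end=tuple(end),
                                      radius=float(rng.integers(0, 3)),
                                      intensity=float(rng.uniform(400, 1000))))
    return VesselPhantomSpec(grid_shape=grid_shape, factors=factors,
                             segments=tuple(segments),
                             n_noise_voxels=n_noise_voxels, seed=seed)
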