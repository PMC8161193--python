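"""Synthetic cohort and multi-station phantom generator.

Because no imaging data accompanies the study this package reimplements, every
downstream stage is exercised against phantoms with known ground truth. The
generator emulates the acquisition structure — contiguous DWI stations (two
b-values, STIR-like fat-suppressed signal model) and Dixon packages on a
deliberately different grid — and a cohort balanced over sex and 10-year age
bands whose marrow %FF/ADC/nSI ground truth follows the published normative
age and sex structure.

Signal model per tissue: ``S(b) = s0 * exp(-b * ADC)`` with ADC in mm^2/s;
Dixon channels ``Fat = k * FF`` and ``Water = k * (100 - FF)``. Noise is
Rician: magnitude of the analytic signal perturbed by two independent
Gaussian components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .config import (ConfigurationError, GeneratorConfig, TissueDefaults,
                     UM2_PER_MM2)
from .geometry import GridGeometry, ImageVolume, write_nifti

LABELS = {"background": 0, "soft_tissue": 1, "marrow": 2, "muscle": 3}
AGE_BANDS = ("30-39", "40-49", "50-59", "60-69", ">=70")

#: Channels written per station by :func:`write_fixture`.
FIXTURE_CHANNELS = ("b50", "b900", "dixon_fat", "dixon_water", "muscle_mask", "labels")


def age_group_of(age: int) -> str:
    """10-year age band label; the final band is open-ended (>=70)."""
    if age < 30 or age > 85:
        raise ValueError(f"age {age} outside the supported range 30-85")
    if age >= 70:
        return AGE_BANDS[-1]
    return AGE_BANDS[(age - 30) // 10]


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    sex: str            # "M" or "F"
    age: int            # years
    bmi: float          # kg/m^2
    low_signal: bool = False   # phantom rendered with marrow s0 reduced

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        age_group_of(self.age)  # range check

    @property
    def age_group(self) -> str:
        return age_group_of(self.age)


@dataclass(frozen=True)
class TissueParams:
    label: str
    true_ff: float      # %
    true_adc: float     # um^2/s
    s0: float           # signal units


@dataclass
class PhantomSpec:
    """Label maps on every station grid plus per-label tissue parameters."""
    meta: SubjectMeta
    tissues: dict            # label name -> TissueParams
    dwi_grids: list          # per-station GridGeometry
    dixon_grids: list
    dwi_labels: list         # per-station uint8 ImageVolume on the DWI grid
    dixon_labels: list
    truth: dict = field(default_factory=dict)   # ground-truth record for the sidecar


@dataclass
class SubjectStudy:
    """One subject's rendered study: per-station image volumes keyed by
    channel name, plus metadata and the ground-truth sidecar record."""
    meta: SubjectMeta
    stations: dict           # channel -> list[ImageVolume], one per station
    truth: dict


# ---------------------------------------------------------------------------
# Cohort sampling

def sample_cohort(n_per_cell: int, seed: int,
                  config: GeneratorConfig = GeneratorConfig()) -> list[SubjectMeta]:
    """Draw a cohort balanced over sex x 10-year age band.

    Ages are uniform integers within each band (the open >=70 band draws from
    70-85); BMI is sex-specific normal truncated below at ``config.bmi_min``.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be a positive integer")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    metas: list[SubjectMeta] = []
    i = 0
    for sex in ("M", "F"):
        for lo, hi in config.age_bands:
            for _ in range(n_per_cell):
                age = int(rng.integers(lo, hi + 1))
                bmi = float(rng.normal(config.bmi_mean[sex], config.bmi_sd[sex]))
                while bmi < config.bmi_min:   # truncation by redraw
                    bmi = float(rng.normal(config.bmi_mean[sex], config.bmi_sd[sex]))
                metas.append(SubjectMeta(subject_id=f"sub-{i:03d}", sex=sex,
                                         age=age, bmi=round(bmi, 1)))
                i += 1
    return metas


def _nsi_b900_mean(meta: SubjectMeta, config: GeneratorConfig) -> float:
    if meta.sex == "M":
        return config.nsi_b900_men_mean
    slope = (config.nsi_b900_women_at70 - config.nsi_b900_women_at30) / 40.0
    return config.nsi_b900_women_at30 + slope * (meta.age - 30)


def _muscle_signal(config: GeneratorConfig, b: float) -> float:
    m = config.muscle
    return m.s0 * float(np.exp(-b * m.true_adc / UM2_PER_MM2))


def marrow_truth(meta: SubjectMeta, config: GeneratorConfig = GeneratorConfig(),
                 rng: np.random.Generator | None = None) -> TissueParams:
    """Ground-truth marrow parameters for one subject.

    Means follow the normative models (%FF = 0.3*Age + 49; ADC = 480 - Age for
    men, 533 - Age for women); between-subject Gaussian noise is added when a
    generator is supplied, and values are clipped to physiologic ranges. The
    marrow ``s0`` is back-computed so the rendered muscle-normalized b900
    signal hits the subject's nSI_b900 target.
    """
    age_group_of(meta.age)  # range check
    ff = config.ff_intercept + config.ff_age_slope * meta.age
    adc = config.adc_intercept[meta.sex] + config.adc_age_slope * meta.age
    nsi = _nsi_b900_mean(meta, config)
    if rng is not None:
        ff += rng.normal(0.0, config.ff_sd)
        adc += rng.normal(0.0, config.adc_sd)
        nsi += rng.normal(0.0, config.nsi_sd)
    ff = float(np.clip(ff, *config.ff_clip))
    adc = float(np.clip(adc, *config.adc_clip))
    nsi = float(max(nsi, config.nsi_floor))
    # s0 such that s0 * exp(-b_high * adc) == nsi * muscle_median_b900
    s0 = nsi * _muscle_signal(config, config.b_high) / float(
        np.exp(-config.b_high * adc / UM2_PER_MM2))
    if meta.low_signal:
        s0 /= config.low_signal_factor
    return TissueParams(label="marrow", true_ff=ff, true_adc=adc, s0=s0)


# ---------------------------------------------------------------------------
# Phantom geometry

def station_grids(config: GeneratorConfig) -> tuple[list[GridGeometry], list[GridGeometry]]:
    """Per-station DWI and Dixon grids.

    Stations are contiguous along z; both contrasts cover the same physical
    extent per station but with different spacings, like the multi-station
    acquisition they emulate. Slice centers are placed symmetrically within
    each station so nearest-slice matching always succeeds.
    """
    L = config.station_length
    dwi, dixon = [], []
    for s in range(config.n_stations):
        z0 = s * L
        dwi.append(GridGeometry(
            origin=(0.0, 0.0, z0 + config.dwi_spacing[2] / 2),
            spacing=config.dwi_spacing, shape=config.dwi_shape))
        dix_span = config.dixon_shape[2] * config.dixon_spacing[2]
        dix_z0 = z0 + (L - dix_span) / 2 + config.dixon_spacing[2] / 2
        dixon.append(GridGeometry(
            origin=(0.0, 0.0, dix_z0),
            spacing=config.dixon_spacing, shape=config.dixon_shape))
    return dwi, dixon


def scene_labels(x: np.ndarray, y: np.ndarray, z: np.ndarray,
                 config: GeneratorConfig) -> np.ndarray:
    """Tissue label at arbitrary physical points (broadcastable arrays)."""
    sc = config.scene
    x, y, z = np.broadcast_arrays(x, y, z)
    lab = np.zeros(x.shape, dtype=np.uint8)

    cx, cy = sc.body_center
    ax, ay = sc.body_semiaxes
    body = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
    lab[body] = LABELS["soft_tissue"]

    in_spine = (body
                & (x >= sc.spine_x[0]) & (x <= sc.spine_x[1])
                & (y >= sc.spine_y[0]) & (y <= sc.spine_y[1])
                & (z >= sc.spine_z[0]) & (z <= sc.spine_z[1]))
    vertebra = np.mod(z - sc.spine_z[0], sc.vertebra_period) < sc.vertebra_length
    lab[in_spine & vertebra] = LABELS["marrow"]

    in_pelvis_x = np.zeros_like(body)
    for x0, x1 in sc.pelvis_x:
        in_pelvis_x |= (x >= x0) & (x <= x1)
    pelvis = (body & in_pelvis_x
              & (y >= sc.pelvis_y[0]) & (y <= sc.pelvis_y[1])
              & (z >= sc.pelvis_z[0]) & (z <= sc.pelvis_z[1]))
    lab[pelvis] = LABELS["marrow"]

    psoas = np.zeros_like(body)
    for px, py in sc.psoas_centers:
        psoas |= (x - px) ** 2 + (y - py) ** 2 <= sc.psoas_radius ** 2
    psoas &= body & (z >= sc.psoas_z[0]) & (z <= sc.psoas_z[1])
    lab[psoas] = LABELS["muscle"]
    return lab


def build_phantom(meta: SubjectMeta, config: GeneratorConfig = GeneratorConfig(),
                  rng: np.random.Generator | None = None) -> PhantomSpec:
    """Assemble label maps on every station grid plus tissue ground truth."""
    config.validate()
    marrow = marrow_truth(meta, config, rng=rng)
    tissues = {
        "marrow": marrow,
        "muscle": TissueParams("muscle", config.muscle.true_ff,
                               config.muscle.true_adc, config.muscle.s0),
        "soft_tissue": TissueParams("soft_tissue", config.soft_tissue.true_ff,
                                    config.soft_tissue.true_adc, config.soft_tissue.s0),
        "background": TissueParams("background", 0.0, 0.0, 0.0),
    }
    dwi_grids, dixon_grids = station_grids(config)

    def render_labels(grids):
        vols = []
        for g in grids:
            X, Y, Z = g.voxel_centers()
            vols.append(ImageVolume(scene_labels(X, Y, Z, config), g, "labels"))
        return vols

    dwi_labels = render_labels(dwi_grids)
    dixon_labels = render_labels(dixon_grids)

    all_lab = np.concatenate([v.data.ravel() for v in dwi_labels])
    n_marrow = int(np.sum(all_lab == LABELS["marrow"]))
    if n_marrow < config.min_marrow_voxels:
        raise ConfigurationError(
            f"grid too small: {n_marrow} marrow voxels < {config.min_marrow_voxels}")
    if set(np.unique(all_lab)) != set(LABELS.values()):
        raise ConfigurationError("phantom must contain all four tissue labels")
    if not any(np.any(v.data == LABELS["muscle"]) for v in dwi_labels):
        raise ConfigurationError("psoas muscle absent from every station")

    truth = {
        "subject_id": meta.subject_id, "sex": meta.sex, "age": meta.age,
        "bmi": meta.bmi, "age_group": meta.age_group,
        "low_signal": meta.low_signal,
        "true_ff": marrow.true_ff, "true_adc": marrow.true_adc,
        "true_nsi_b900": marrow.s0
        * float(np.exp(-config.b_high * marrow.true_adc / UM2_PER_MM2))
        / _muscle_signal(config, config.b_high),
        "true_nsi_b50": marrow.s0
        * float(np.exp(-config.b_low * marrow.true_adc / UM2_PER_MM2))
        / _muscle_signal(config, config.b_low),
        "marrow_s0": marrow.s0,
    }
    return PhantomSpec(meta=meta, tissues=tissues, dwi_grids=dwi_grids,
                       dixon_grids=dixon_grids, dwi_labels=dwi_labels,
                       dixon_labels=dixon_labels, truth=truth)


# ---------------------------------------------------------------------------
# Rendering

def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return signal
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt(re ** 2 + im ** 2)


def _per_label(labels: np.ndarray, values: dict) -> np.ndarray:
    lut = np.zeros(max(LABELS.values()) + 1, dtype=np.float64)
    for name, idx in LABELS.items():
        lut[idx] = values[name]
    return lut[labels]


def render_study(phantom: PhantomSpec, noise_sigma: float = 0.0, seed: int = 0,
                 config: GeneratorConfig = GeneratorConfig()) -> SubjectStudy:
    """Render DWI (b50/b900), Dixon (Fat/Water), muscle mask and truth labels
    for every station. Noiseless rendering is exactly the analytic signal."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51]))
    t = phantom.tissues

    def dwi_signal(b):
        return {name: p.s0 * float(np.exp(-b * p.true_adc / UM2_PER_MM2))
                for name, p in t.items()}

    b_low, b_high = config.b_low, config.b_high
    stations: dict[str, list[ImageVolume]] = {c: [] for c in FIXTURE_CHANNELS}
    k = config.dixon_k
    for s, (g_dwi, g_dix) in enumerate(zip(phantom.dwi_grids, phantom.dixon_grids)):
        lab_dwi = phantom.dwi_labels[s].data
        lab_dix = phantom.dixon_labels[s].data
        for b, chan in ((b_low, "b50"), (b_high, "b900")):
            sig = _per_label(lab_dwi, dwi_signal(b))
            stations[chan].append(ImageVolume(
                _rician(sig, noise_sigma, rng).astype(np.float32), g_dwi, chan))
        ff = {name: p.true_ff for name, p in t.items()}
        fat = _per_label(lab_dix, {n: k * v for n, v in ff.items()})
        water = _per_label(lab_dix, {n: (k * (100.0 - v) if n != "background" else 0.0)
                                     for n, v in ff.items()})
        stations["dixon_fat"].append(ImageVolume(
            _rician(fat, noise_sigma, rng).astype(np.float32), g_dix, "dixon_fat"))
        stations["dixon_water"].append(ImageVolume(
            _rician(water, noise_sigma, rng).astype(np.float32), g_dix, "dixon_water"))
        stations["muscle_mask"].append(ImageVolume(
            lab_dwi == LABELS["muscle"], g_dwi, "mask"))
        stations["labels"].append(ImageVolume(lab_dwi, g_dwi, "labels"))
    return SubjectStudy(meta=phantom.meta, stations=stations, truth=dict(phantom.truth))


def simulate_subject(meta: SubjectMeta, config: GeneratorConfig = GeneratorConfig(),
                     seed: int = 0) -> SubjectStudy:
    """Convenience: phantom + render with subject-specific derived seeds."""
    ss = np.random.SeedSequence([int(seed), _stable_id(meta.subject_id)])
    truth_rng = np.random.default_rng(ss.spawn(1)[0])
    phantom = build_phantom(meta, config, rng=truth_rng)
    render_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    return render_study(phantom, noise_sigma=config.noise_sigma, seed=render_seed,
                        config=config)


def simulate_cohort(n_per_cell: int, seed: int,
                    config: GeneratorConfig = GeneratorConfig(),
                    low_signal_fraction: float = 0.0,
                    noise_sigma: float | None = None):
    """Yield rendered studies for a balanced cohort (lazily, for memory)."""
    metas = sample_cohort(n_per_cell, seed, config)
    if low_signal_fraction > 0:
        pick = np.random.default_rng(np.random.SeedSequence([int(seed), 0x10])) \
            .random(len(metas)) < low_signal_fraction
        metas = [SubjectMeta(m.subject_id, m.sex, m.age, m.bmi, low_signal=bool(p))
                 for m, p in zip(metas, pick)]
    if noise_sigma is not None:
        config = GeneratorConfig(**{**_as_kwargs(config), "noise_sigma": noise_sigma})
    for meta in metas:
        yield simulate_subject(meta, config, seed=seed)


def _as_kwargs(config: GeneratorConfig) -> dict:
    import dataclasses
    return {f.name: getattr(config, f.name) for f in dataclasses.fields(config)}


def _stable_id(subject_id: str) -> int:
    import zlib
    return zlib.crc32(subject_id.encode()) % (2 ** 31)


# ---------------------------------------------------------------------------
# Fixture I/O

def write_fixture(study: SubjectStudy, out_dir) -> dict:
    """Write one NIfTI per station per channel plus a JSON sidecar carrying
    subject metadata and ground truth. Returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"subject_id": study.meta.subject_id, "files": {}, "n_stations": 0}
    n_stations = len(study.stations["b50"])
    manifest["n_stations"] = n_stations
    for chan in FIXTURE_CHANNELS:
        paths = []
        for s, vol in enumerate(study.stations[chan]):
            p = out / f"{study.meta.subject_id}_station-{s}_{chan}.nii.gz"
            write_nifti(vol, p)
            paths.append(p.name)
        manifest["files"][chan] = paths
    sidecar = {"meta": asdict(study.meta), "truth": study.truth}
    sidecar_path = out / f"{study.meta.subject_id}_sidecar.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    manifest["sidecar"] = sidecar_path.name
    (out / f"{study.meta.subject_id}_manifest.json").write_text(
        json.dumps(manifest, indent=1))
    return manifest
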