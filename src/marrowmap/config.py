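"""Configuration for the phantom generator and the processing pipeline.

Every constant the pipeline or generator relies on lives here: acquisition
b-values, the marrow-mask refinement thresholds (ADC <= 1000 um^2/s,
%FF >= 15%), the tissue ground-truth models of the synthetic cohort, and the
scaled-down station geometry. Values marked "calibration choice" are not
literature claims; they are tuned only to the published cohort summary
statistics (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict

#: Conversion between the fitting unit (mm^2/s) and the reporting unit (um^2/s).
UM2_PER_MM2 = 1.0e6


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TissueDefaults:
    """Fixed ground truth for one non-marrow tissue class."""
    true_ff: float      # %
    true_adc: float     # um^2/s
    s0: float           # signal units at b=0


@dataclass(frozen=True)
class SceneSpec:
    """Simplified axial-skeleton scene, in patient mm coordinates.

    A spine-like column of vertebral cuboids separated by soft-tissue discs,
    two pelvis-like marrow blocks, paired psoas-like muscle cylinders, all
    embedded in an elliptical soft-tissue body. Margins are large enough that
    marrow never borders muscle or background, so in-plane interpolation of
    the %FF map at marrow voxels only ever mixes marrow with soft tissue.
    """
    body_center: tuple[float, float] = (96.0, 100.0)
    body_semiaxes: tuple[float, float] = (85.0, 75.0)
    spine_x: tuple[float, float] = (81.0, 111.0)
    spine_y: tuple[float, float] = (118.0, 148.0)
    spine_z: tuple[float, float] = (15.0, 345.0)
    vertebra_period: float = 30.0      # mm; one vertebra + disc
    vertebra_length: float = 26.0      # mm of marrow per period
    pelvis_x: tuple[tuple[float, float], ...] = ((26.0, 66.0), (126.0, 166.0))
    pelvis_y: tuple[float, float] = (95.0, 135.0)
    pelvis_z: tuple[float, float] = (190.0, 240.0)
    psoas_centers: tuple[tuple[float, float], ...] = ((61.0, 70.0), (131.0, 70.0))
    psoas_radius: float = 11.0
    psoas_z: tuple[float, float] = (120.0, 260.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-cohort defaults.

    The marrow models restate the published normative structure: %FF mean
    0.3*Age + 49 (between-subject SD 5.7%), ADC mean 480 - Age for men and
    533 - Age for women (SD 40 um^2/s). The nSI_b900 model is a calibration
    choice: men constant 2.9, women declining linearly from 4.6 at age 30 to
    2.9 at age 70 (extrapolated linearly beyond 70), SD 0.7, floored at 2.0.
    """

    # cohort structure
    age_bands: tuple[tuple[int, int], ...] = (
        (30, 39), (40, 49), (50, 59), (60, 69), (70, 85))
    bmi_mean: dict = field(default_factory=lambda: {"M": 25.6, "F": 23.3})
    bmi_sd: dict = field(default_factory=lambda: {"M": 3.3, "F": 3.3})
    bmi_min: float = 15.0

    # marrow ground-truth models
    ff_intercept: float = 49.0
    ff_age_slope: float = 0.3
    ff_sd: float = 5.7                      # % ; yields total SD ~7.2 over ages 30-85
    ff_clip: tuple[float, float] = (15.0, 95.0)
    adc_intercept: dict = field(default_factory=lambda: {"M": 480.0, "F": 533.0})
    adc_age_slope: float = -1.0             # um^2/s per year, both sexes
    adc_sd: float = 40.0                    # um^2/s between subjects
    adc_clip: tuple[float, float] = (100.0, 1000.0)
    nsi_b900_men_mean: float = 2.9          # calibration choice
    nsi_b900_women_at30: float = 4.6        # calibration choice
    nsi_b900_women_at70: float = 2.9        # calibration choice
    nsi_sd: float = 0.7
    nsi_floor: float = 2.0                  # keeps default phantoms segmentable

    # fixed non-marrow tissues (literature-typical)
    muscle: TissueDefaults = TissueDefaults(true_ff=8.0, true_adc=1400.0, s0=1000.0)
    soft_tissue: TissueDefaults = TissueDefaults(true_ff=85.0, true_adc=900.0, s0=600.0)

    # signal model
    b_low: float = 50.0                     # s/mm^2
    b_high: float = 900.0                   # s/mm^2
    dixon_k: float = 10.0                   # signal units per %FF point
    noise_sigma: float = 15.0               # Rician sigma, signal units
    low_signal_factor: float = 3.0          # marrow s0 divisor in low-signal mode

    # station geometry (scaled-down grids, deliberately mismatched DWI/Dixon)
    n_stations: int = 3
    dwi_shape: tuple[int, int, int] = (48, 48, 20)
    dwi_spacing: tuple[float, float, float] = (4.0, 4.0, 6.0)
    dixon_shape: tuple[int, int, int] = (64, 64, 34)
    dixon_spacing: tuple[float, float, float] = (3.0, 3.0, 3.5)
    min_marrow_voxels: int = 500
    scene: SceneSpec = SceneSpec()

    @property
    def station_length(self) -> float:
        return self.dwi_shape[2] * self.dwi_spacing[2]

    def validate(self) -> None:
        if self.n_stations < 1:
            raise ConfigurationError("n_stations must be >= 1")
        ip_dwi = tuple(n * s for n, s in zip(self.dwi_shape[:2], self.dwi_spacing[:2]))
        ip_dix = tuple(n * s for n, s in zip(self.dixon_shape[:2], self.dixon_spacing[:2]))
        if ip_dwi != ip_dix:
            raise ConfigurationError(
                f"DWI and Dixon grids must cover the same in-plane extent "
                f"({ip_dwi} vs {ip_dix})")


#: A small-grid configuration for fast tests; same physical extent per
#: station, coarser sampling, fewer stations.
def tiny_generator_config(**overrides) -> GeneratorConfig:
    defaults = dict(
        n_stations=2,
        dwi_shape=(24, 24, 10), dwi_spacing=(8.0, 8.0, 12.0),
        dixon_shape=(32, 32, 17), dixon_spacing=(6.0, 6.0, 7.0),
        min_marrow_voxels=100,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@dataclass(frozen=True)
class PipelineConfig:
    """Processing-stage constants.

    ``adc_max``/``ff_min`` are the published marrow-mask refinement
    thresholds; ``cdwi_b_target`` is the virtual b-value of the computed
    high-b image used for segmentation (vendor value unpublished; 1500 s/mm^2
    by default).
    """

    b_low: float = 50.0
    b_high: float = 900.0
    cdwi_b_target: float = 1500.0
    adc_max: float = 1000.0                 # um^2/s
    ff_min: float = 15.0                    # %
    ff_epsilon: float = 1e-9                # signal units; below -> %FF undefined
    stations_to_process: tuple[int, ...] | None = None   # None = all lower-body stations in the fixture
    threshold: str | float = "auto"         # Otsu, or a manual signal threshold
    largest_component: bool = False
    qc_min_voxels: int = 100
    qc_min_ratio: float = 1.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.adc_max <= 0:
            raise ConfigurationError("adc_max must be positive")
        if not (0 <= self.ff_min < 100):
            raise ConfigurationError("ff_min must be in [0, 100)")
        if self.b_high <= self.b_low:
            raise ConfigurationError("b_high must exceed b_low")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["stations_to_process"] is not None:
            d["stations_to_process"] = list(d["stations_to_process"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("stations_to_process") is not None:
            d["stations_to_process"] = tuple(d["stations_to_process"])
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})
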