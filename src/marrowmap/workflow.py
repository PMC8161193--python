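"""Pipeline orchestration: subject I/O, per-subject processing chain, and
cohort assembly.

Per-subject chain (all constants from :class:`~marrowmap.config.PipelineConfig`):

1. stack the DWI stations (b50, b900, muscle mask) into whole-body volumes;
2. muscle medians from the psoas mask (independent of the marrow pipeline);
3. ADC map from the b50/b900 pair; computed high-b image at the cDWI target;
4. threshold segmentation of the computed high-b stack;
5. %FF per Dixon station, resampled slice-matched onto the DWI station grid,
   then stacked;
6. mask refinement (ADC <= adc_max, %FF >= ff_min);
7. muscle normalization of both DW channels and per-subject medians.

QC-failed subjects are retained in the cohort table with
``segmentation_ok = False`` (replacement is a cohort-level decision, exposed
separately in :func:`assemble_balanced`).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohortstats
from .config import PipelineConfig
from .extract import (ProcessingError, SubjectMeasurements, muscle_medians,
                      normalize_si, subject_summary)
from .geometry import read_nifti
from .marrowseg import (Mask, QCReport, body_mask_from_total, qc_subject,
                        refine_mask, threshold_segment)
from .parammaps import compute_adc, compute_cdwi, compute_ff
from .spatial import resample_to_grid, stack_stations
from .synthcohort import FIXTURE_CHANNELS, SubjectMeta, SubjectStudy

log = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "subject_id", "sex", "age", "age_group", "bmi",
    "median_ff", "median_nsi_b50", "median_nsi_b900", "median_adc",
    "marrow_voxels", "muscle_median_b50", "muscle_median_b900",
    "segmentation_ok",
]


class LoadError(RuntimeError):
    pass


def read_subject(subject_dir, subject_id: str | None = None) -> SubjectStudy:
    """Load a fixture subject (NIfTI stations + JSON sidecar) back into memory."""
    d = Path(subject_dir)
    manifests = sorted(d.glob("*_manifest.json"))
    if subject_id is not None:
        manifests = [m for m in manifests if m.name.startswith(subject_id)]
    if not manifests:
        raise LoadError(f"no manifest found in {d}")
    manifest = json.loads(manifests[0].read_text())
    sidecar = json.loads((d / manifest["sidecar"]).read_text())
    meta = SubjectMeta(**sidecar["meta"])
    stations: dict[str, list] = {}
    for chan in FIXTURE_CHANNELS:
        if chan not in manifest["files"]:
            raise LoadError(f"fixture for {meta.subject_id} missing channel {chan!r}")
        io_chan = {"muscle_mask": "mask", "b50": "b50", "b900": "b900",
                   "dixon_fat": "dixon_fat", "dixon_water": "dixon_water",
                   "labels": "labels"}[chan]
        stations[chan] = [read_nifti(d / name, io_chan)
                          for name in manifest["files"][chan]]
    return SubjectStudy(meta=meta, stations=stations, truth=sidecar["truth"])


def _select_stations(vols: list, config: PipelineConfig) -> list:
    if config.stations_to_process is None:
        return vols
    return [vols[i] for i in config.stations_to_process]


def run_subject(study: SubjectStudy, config: PipelineConfig = PipelineConfig()
                ) -> tuple[SubjectMeasurements | None, QCReport, dict]:
    """Execute the full per-subject chain; returns (measurements, QC report,
    cohort-table row). Measurements are None when the subject fails QC with
    an empty refined mask."""
    meta = study.meta
    b50 = stack_stations(_select_stations(study.stations["b50"], config))
    b900 = stack_stations(_select_stations(study.stations["b900"], config))
    muscle = Mask(stack_stations(
        _select_stations(study.stations["muscle_mask"], config)).data,
        b50.geometry, "external")

    m50, m900 = muscle_medians(b50, b900, muscle)
    adc = compute_adc(b50, b900, config.b_low, config.b_high)
    cdwi = compute_cdwi(b900, adc, config.b_high, config.cdwi_b_target)

    ff_stations, total_stations = [], []
    for fat, water, g_dwi in zip(
            _select_stations(study.stations["dixon_fat"], config),
            _select_stations(study.stations["dixon_water"], config),
            [v.geometry for v in _select_stations(study.stations["b50"], config)]):
        ff_dixon = compute_ff(fat, water, epsilon=config.ff_epsilon)
        ff_stations.append(resample_to_grid(ff_dixon, g_dwi, mode="linear"))
        total = fat.with_data(np.asarray(fat.data, float)
                              + np.asarray(water.data, float), "total")
        total_stations.append(resample_to_grid(total, g_dwi, mode="linear"))
    ff = stack_stations(ff_stations)

    # Otsu assumes two classes; restrict its histogram to the body (from the
    # Dixon total signal) so the air/body contrast cannot dominate.
    body = body_mask_from_total(stack_stations(total_stations))
    mask, thr = threshold_segment(cdwi, config.threshold,
                                  config.largest_component, within=body)

    refined, counts = refine_mask(mask, adc, ff, config.adc_max, config.ff_min)
    qc = qc_subject(meta.subject_id, refined, b900, m900,
                    min_voxels=config.qc_min_voxels, min_ratio=config.qc_min_ratio)
    log.info("%s: threshold %.1f, mask %d -> refined %d voxels, QC %s",
             meta.subject_id, thr, counts["input"], counts["kept"],
             "ok" if qc.segmentation_ok else "FAILED")

    row = {"subject_id": meta.subject_id, "sex": meta.sex, "age": meta.age,
           "age_group": meta.age_group, "bmi": meta.bmi,
           "segmentation_ok": qc.segmentation_ok}
    try:
        nsi50 = normalize_si(b50, m50)
        nsi900 = normalize_si(b900, m900)
        meas = subject_summary(adc, ff, nsi50, nsi900, refined, meta, m50, m900)
        row.update(meas.as_dict())
        row.pop("subject_id", None)
        row["subject_id"] = meta.subject_id
    except ProcessingError:
        meas = None
        row.update({k: np.nan for k in ("median_ff", "median_nsi_b50",
                                        "median_nsi_b900", "median_adc",
                                        "muscle_median_b50", "muscle_median_b900")})
        row["marrow_voxels"] = refined.count
        row["segmentation_ok"] = False
    return meas, qc, {k: row[k] for k in COHORT_COLUMNS}


def process_cohort(studies, config: PipelineConfig = PipelineConfig()
                   ) -> pd.DataFrame:
    """Run the per-subject chain over an iterable of studies (lazily)."""
    rows = [run_subject(study, config)[2] for study in studies]
    if not rows:
        raise RuntimeError("no usable subjects")
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def assemble_balanced(table: pd.DataFrame, n_per_cell: int | None = None
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Cohort-level replacement policy: within each sex x age-band cell,
    prefer QC-passing subjects; failed subjects are replaced by passing
    spares of the same cell when available. Returns (table, replacement log).
    """
    if n_per_cell is None:
        return table.reset_index(drop=True), []
    kept, replaced = [], []
    for (sex, band), cell in table.groupby(["sex", "age_group"], sort=True):
        ok = cell[cell.segmentation_ok]
        bad = cell[~cell.segmentation_ok]
        chosen = ok.head(n_per_cell)
        if len(chosen) < n_per_cell:   # not enough spares: keep flagged rows
            chosen = pd.concat([chosen, bad.head(n_per_cell - len(chosen))])
        replaced.extend(sorted(set(bad.subject_id) - set(chosen.subject_id)))
        kept.append(chosen)
    return pd.concat(kept).reset_index(drop=True), replaced


def cohort_statistics(table: pd.DataFrame, config: PipelineConfig = PipelineConfig(),
                      include_failed: bool = False) -> dict:
    """The full statistics bundle on a cohort table (JSON-serializable)."""
    df = table if include_failed else table[table.segmentation_ok]
    df = df.dropna(subset=list(cohortstats.PARAMETERS))
    bundle: dict = {"n": int(len(df)), "config": config.to_dict()}

    def _try(key, fn):
        try:
            bundle[key] = fn()
        except ValueError as exc:     # cohort too small / degenerate for this block
            log.warning("cohort statistics: %s skipped (%s)", key, exc)
            bundle[key] = {"error": str(exc)}

    _try("reference_limits", lambda: {
        p: cohortstats.reference_limits(df[p], parameter=p,
                                        alpha=config.alpha).as_dict()
        for p in cohortstats.PARAMETERS})
    _try("sex_comparison", lambda: {
        p: cohortstats.mann_whitney(df.loc[df.sex == "M", p],
                                    df.loc[df.sex == "F", p]).as_dict()
        for p in cohortstats.PARAMETERS})

    def _age_corr():
        out = {}
        for p in cohortstats.PARAMETERS:
            per = {"all": cohortstats.spearman(df.age, df[p]).as_dict()}
            for sex in ("M", "F"):
                sub = df[df.sex == sex]
                per[sex] = cohortstats.spearman(sub.age, sub[p]).as_dict()
            out[p] = per
        return out

    _try("age_correlation", _age_corr)
    _try("ancova", lambda: {
        p: cohortstats.ancova(df, p, interaction=True).as_dict()
        for p in cohortstats.PARAMETERS})
    _try("normative_models", lambda: {
        k: v.as_dict() for k, v in cohortstats.fit_normative(df).items()})
    _try("group_comparisons", lambda: {
        p: [r.as_dict() for r in cohortstats.group_compare(df, p)]
        for p in cohortstats.PARAMETERS})
    return bundle


def run_cohort(fixture_root, config: PipelineConfig = PipelineConfig(),
               out_dir=None, n_per_cell: int | None = None
               ) -> tuple[pd.DataFrame, dict]:
    """Process every fixture subject under ``fixture_root``; write the cohort
    CSV and results bundle to ``out_dir`` if given."""
    root = Path(fixture_root)
    manifests = sorted(root.rglob("*_manifest.json"))
    if not manifests:
        raise RuntimeError(f"no subjects found under {root}")
    studies = (read_subject(m.parent, m.name.split("_manifest")[0])
               for m in manifests)
    table = process_cohort(studies, config)
    table, replaced = assemble_balanced(table, n_per_cell)
    if replaced:
        log.info("replaced %d QC-failed subjects: %s", len(replaced), replaced)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort.csv", index=False)
    bundle = cohort_statistics(table, config)
    bundle["replaced_subjects"] = replaced
    if out_dir is not None:
        (out / "results.json").write_text(json.dumps(bundle, indent=1))
    return table, bundle
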