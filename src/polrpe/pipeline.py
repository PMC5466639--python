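"""End-to-end analysis pipeline and report bundle.

simulate -> Stokes/DOPU -> en-face projections -> PS-SLO depolarized image ->
HRF/PED volumetry -> four-modality classification -> cohort summary tables
and statistics.  The whole pipeline is a pure function of (config, seed):
rerunning with the same configuration and seed reproduces every table
bitwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, replace

import numpy as np
import pandas as pd

from . import __version__
from .classify import (ClassificationThresholds, EyeRecord, FocusObservation,
                       classify_eye, classify_focus, detect_low_dopu_masses,
                       score_focus_modalities)
from .enface import (composite_dopu_overlay, log_compress, mean_intensity_projection,
                     min_dopu_projection)
from .params import GROUPS, OpticParams
from .polarimetry import KernelSpec, compute_dopu, estimate_noise, stokes_from_fields
from .psslo import depolarized_light_image
from .quant import (binarize_bscan, cavalieri_ped_volume, measure_hrf_volume,
                    ped_areas_from_segmentation, truth_guided_regions)
from .synthetic import PhantomConfig, SyntheticEyeDataset, iter_cohort

#: Desk-scale grid used by the demo configuration and the validation cohorts.
DESK_PARAMS = OpticParams(n_alines=96, n_bscans=48, n_depth=128, n_repeats=4)

DEFAULT_CONFIG = {
    "cohort": {"serous_ped": 3, "drusenoid_ped": 3, "early_intermediate": 2,
               "remission": 1, "fibrosis": 1},
    "optics": {},
    "thresholds": {},
    "n_psslo_angles": 8,
    "speckle": True,
    "save_images": False,
}


def analyze_eye(
    ds: SyntheticEyeDataset,
    thresholds: ClassificationThresholds | None = None,
    kernel: KernelSpec | None = None,
) -> tuple[EyeRecord, list[FocusObservation], dict]:
    """Run the full single-eye analysis.

    Returns the eye record, the labeled focus observations and a dict of
    intermediate artifacts (DOPU volume, projections, depolarized image,
    binarized volume) for inspection or export.
    """
    thresholds = thresholds or ClassificationThresholds()
    kernel = kernel or KernelSpec()
    p = ds.params

    stokes = stokes_from_fields(ds.fields)
    vit = np.zeros(p.shape, dtype=bool)
    vit[:, :, : ds.vitreous_max_z] = True
    noise = estimate_noise(ds.fields, vit)
    dopu = compute_dopu(stokes, kernel, noise, corrected=True)

    proj_whole = min_dopu_projection(dopu)
    proj_anterior = min_dopu_projection(dopu, ds.segmentation)
    proj_intensity = mean_intensity_projection(stokes)
    depol = depolarized_light_image(ds.psslo)

    # volumetry: Shanbhag binarization of each log-compressed mean B-scan,
    # truth-guided HRF selection, Cavalieri PED volume from the segmentation
    mean_s0 = stokes.s0.mean(axis=0)  # (x, b, z)
    binary = np.zeros(p.shape, dtype=bool)
    for b in range(p.n_bscans):
        binary[:, b, :] = binarize_bscan(log_compress(mean_s0[:, b, :]))
    truth_mask = ds.truth.focus_union_mask(p.shape)
    hrf_vol = measure_hrf_volume(truth_guided_regions(binary, truth_mask), p)

    ped_vol = math.nan
    if ds.truth.ped_kind != "none":
        areas = ped_areas_from_segmentation(ds.segmentation.line,
                                            ds.truth.rpe_base_depth, p)
        ped_vol = cavalieri_ped_volume(areas, p.pitch_b).value_mm3

    exclusion = truth_mask
    masses = detect_low_dopu_masses(dopu, ds.segmentation, thresholds, exclusion)
    all_fp = truth_mask.any(axis=2)
    observations = []
    for i, ft in enumerate(ds.truth.foci):
        obs = score_focus_modalities(
            i, ft.voxels, dopu, depol.display, ds.nir_af, ds.sw_af,
            thresholds, p, all_footprints=all_fp)
        observations.append(classify_focus(obs, thresholds, mass_footprints=masses))

    record = classify_eye(ds.eye_id, ds.group, observations,
                          hrf_volume_mm3=hrf_vol.value_mm3,
                          ped_volume_mm3=ped_vol)
    artifacts = {
        "dopu": dopu,
        "noise": noise,
        "min_dopu_whole": proj_whole,
        "min_dopu_anterior": proj_anterior,
        "mean_intensity": proj_intensity,
        "depolarized": depol,
        "binary": binary,
    }
    return record, observations, artifacts


def _focus_rows(eye_id: str, group: str, observations, truth_foci) -> list[dict]:
    rows = []
    for obs, ft in zip(observations, truth_foci):
        rows.append({
            "eye_id": eye_id, "group": group, "focus_id": obs.focus_id,
            "min_dopu": obs.min_dopu, "psslo_z": obs.psslo_z,
            "nir_z": obs.nir_z, "sw_z": obs.sw_z, "label": obs.label,
            "migration_truth": ft.migration,
        })
    return rows


def run_pipeline(config: dict | None = None, seed: int = 0,
                 out_dir=None) -> dict:
    """Execute the full pipeline on a simulated cohort and build the report.

    ``config`` may override the cohort composition, optics, thresholds and
    output options (see ``DEFAULT_CONFIG``).  Writes CSV tables, a JSON run
    log and (optionally) per-eye images under ``out_dir``.
    """
    from . import io as pio
    from . import stats as pstats

    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    cohort_spec = {g: int(n) for g, n in cfg["cohort"].items()}
    if sum(cohort_spec.values()) == 0:
        raise ValueError("empty report: cohort configuration has no eyes")
    params = replace(DESK_PARAMS, **cfg.get("optics", {}))
    thresholds = ClassificationThresholds(**cfg.get("thresholds", {}))
    phantom_cfg = PhantomConfig(**cfg.get("phantom", {}))

    records, focus_rows, first_artifacts = [], [], None
    datasets_meta = []
    for ds in iter_cohort(cohort_spec, params=params, seed=seed,
                          config=phantom_cfg,
                          n_psslo_angles=int(cfg["n_psslo_angles"]),
                          speckle=bool(cfg["speckle"])):
        record, observations, artifacts = analyze_eye(ds, thresholds)
        records.append(record)
        focus_rows.extend(_focus_rows(ds.eye_id, ds.group, observations, ds.truth.foci))
        datasets_meta.append({"eye_id": ds.eye_id, "group": ds.group,
                              "n_foci_truth": len(ds.truth.foci),
                              "true_ped_volume_mm3": ds.truth.ped_volume_mm3})
        if first_artifacts is None:
            first_artifacts = (ds, artifacts)

    eye_df = pd.DataFrame([asdict(r) for r in records])
    focus_df = pd.DataFrame(focus_rows)
    counts = pstats.summarize_counts(records)
    volumes = pstats.summarize_volumes(records)

    stats_out: dict = {}
    for g in [g for g in GROUPS if g in set(eye_df["group"])]:
        try:
            stat, df_, p = pstats.chi_square_group_vs_rest(records, g)
            stats_out[f"chi2_migration_{g}_vs_rest"] = {
                "statistic": stat, "df": df_, "p": p}
        except ValueError:
            stats_out[f"chi2_migration_{g}_vs_rest"] = None
    groups_present = [g for g in GROUPS if g in set(eye_df["group"])]
    if len(groups_present) >= 2:
        vols = [eye_df.loc[eye_df["group"] == g, "hrf_volume_mm3"].to_numpy()
                for g in groups_present]
        h, p = pstats.kruskal_wallis(*vols)
        stats_out["kruskal_wallis_hrf_volume"] = {"H": h, "p": p}
    serous = eye_df[eye_df["group"] == "serous_ped"]
    if len(serous) >= 3:
        try:
            r, r2, p = pstats.pearson_r2(serous["ped_volume_mm3"],
                                         serous["hrf_volume_mm3"])
            stats_out["pearson_serous_hrf_vs_ped"] = {"r": r, "r2": r2, "p": p}
        except ValueError:
            stats_out["pearson_serous_hrf_vs_ped"] = None

    report = {
        "eye_records": eye_df,
        "focus_observations": focus_df,
        "group_counts": counts,
        "group_volumes": volumes,
        "stats": stats_out,
        "truth": pd.DataFrame(datasets_meta),
        "config": cfg,
        "seed": seed,
    }
    if out_dir is not None:
        pio.write_report(report, out_dir, version=__version__,
                         first_eye=first_artifacts if cfg.get("save_images") else None)
    return report
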