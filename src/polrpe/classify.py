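"""Four-modality concordance classification of hyperreflective foci.

A focus counts as intraretinal RPE migration only when all four modalities
agree at its location: low DOPU on PS-OCT (melanin depolarization), elevated
signal in the PS-SLO depolarized light image, and hyper-autofluorescence on
both NIR-AF (melanin/melanolipofuscin) and SW-AF (lipofuscin/melanolipofuscin).
Foci whose axial column overlaps a large connected low-DOPU mass (the
hard-exudate signature) are excluded from classification altogether.

The study's subjective observer grading is replaced by thresholded z-scores
against a local background annulus; a second "observer" is realized by
perturbing the thresholds, which supports interobserver-agreement (Cohen's
kappa) experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .enface import SegmentationLine
from .params import OpticParams
from .polarimetry import DopuVolume


@dataclass(frozen=True)
class ClassificationThresholds:
    """Operating points of the automatic grader.

    dopu_low is the printed low-DOPU cutoff (< 0.8, strict).  The z-score
    multipliers and the mass size are surrogates for the study's observer
    judgment.  The background annulus is defined by distances (um) from the
    focus footprint; the mass search is restricted to depths more than
    mass_margin_voxels anterior to the RPE segmentation line so that the
    physiologic RPE/choroid depolarization (and the kernel's depth bleed just
    above it) never masquerades as an exudate mass.
    """

    dopu_low: float = 0.8
    af_z: float = 2.0
    psslo_z: float = 2.0
    mass_min_voxels: int = 200
    annulus_inner_um: float = 25.0
    annulus_outer_um: float = 150.0
    mass_margin_voxels: int = 3
    #: lateral dilation (x, b pixels) of the focus footprint when testing the
    #: mass-overlap exclusion: a mass engulfing a focus is blanked by the
    #: focus voxels in the focus's own columns, so adjacency still counts as
    #: "corresponding axial location"
    mass_overlap_dilation_px: tuple[int, int] = (2, 1)

    def __post_init__(self) -> None:
        if not 0.0 < self.dopu_low < 1.0:
            raise ValueError("dopu_low must be in (0, 1)")
        if self.af_z <= 0 or self.psslo_z <= 0:
            raise ValueError("z-score multipliers must be > 0")


@dataclass
class FocusObservation:
    """One HRF with its voxel set, en-face footprint, modality scores and label."""

    focus_id: int
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]  # (x, b, z) index arrays
    footprint: np.ndarray  # (x, b) bool
    min_dopu: float = math.nan
    psslo_z: float = math.nan
    nir_z: float = math.nan
    sw_z: float = math.nan
    excluded_mass: bool = False
    label: str | None = None  # migration | no_migration | excluded


@dataclass
class EyeRecord:
    """Eye-level tally feeding the cohort tables.

    The migration / no-migration columns are mutually exclusive with
    migration precedence; excluded foci are ignored for the tallies.
    """

    eye_id: str
    group: str
    has_migrating_hrf: bool
    has_nonmigrating_hrf: bool
    hrf_volume_mm3: float
    ped_volume_mm3: float = math.nan
    n_foci: int = 0
    n_excluded: int = 0


def _zscore(image: np.ndarray, footprint: np.ndarray, background: np.ndarray) -> float:
    img = np.asarray(image, dtype=float)
    mu_f = img[footprint].mean()
    bg = img[background]
    mu_b = bg.mean()
    sd_b = max(bg.std(), 1e-6)
    return float((mu_f - mu_b) / sd_b)


def _background_annulus(
    footprint: np.ndarray,
    all_footprints: np.ndarray,
    thresholds: ClassificationThresholds,
    params: OpticParams,
) -> np.ndarray:
    dist_um = ndimage.distance_transform_edt(
        ~footprint, sampling=(params.pitch_x, params.pitch_b)
    )
    annulus = (
        (dist_um >= thresholds.annulus_inner_um)
        & (dist_um <= thresholds.annulus_outer_um)
        & ~all_footprints
    )
    if annulus.sum() < 20:  # fall back to the full non-focus background
        annulus = ~all_footprints
    return annulus


def score_focus_modalities(
    focus_id: int,
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray],
    dopu: DopuVolume,
    psslo_image: np.ndarray,
    nir_af: np.ndarray,
    sw_af: np.ndarray,
    thresholds: ClassificationThresholds,
    params: OpticParams,
    all_footprints: np.ndarray | None = None,
) -> FocusObservation:
    """Score one focus against the four modalities (unlabeled).

    En-face scores are z-scores of the footprint mean against a background
    annulus that excludes every focus footprint; the PS-OCT score is the
    minimum DOPU over the focus's valid voxels.
    """
    xs, bs, zs = (np.asarray(v, dtype=int) for v in voxels)
    if xs.size == 0:
        raise ValueError("focus footprint/voxel set is empty")
    footprint = np.zeros(psslo_image.shape, dtype=bool)
    footprint[xs, bs] = True
    if all_footprints is None:
        all_footprints = footprint
    background = _background_annulus(footprint, all_footprints, thresholds, params)

    vals = dopu.values[xs, bs, zs]
    valid = dopu.valid[xs, bs, zs]
    min_dopu = float(vals[valid].min()) if valid.any() else math.nan

    return FocusObservation(
        focus_id=focus_id,
        voxels=(xs, bs, zs),
        footprint=footprint,
        min_dopu=min_dopu,
        psslo_z=_zscore(psslo_image, footprint, background),
        nir_z=_zscore(nir_af, footprint, background),
        sw_z=_zscore(sw_af, footprint, background),
    )


def detect_low_dopu_masses(
    dopu: DopuVolume,
    segmentation: SegmentationLine,
    thresholds: ClassificationThresholds,
    focus_exclusion: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Connected low-DOPU components of at least mass_min_voxels, strictly
    anterior to the RPE (with a margin), outside the (kernel-dilated) focus
    voxel sets.  Returns their en-face footprints."""
    nx, nb, nz = dopu.values.shape
    zidx = np.arange(nz)[None, None, :]
    anterior = zidx < (segmentation.line[:, :, None] - thresholds.mass_margin_voxels)
    cand = dopu.valid & (dopu.values < thresholds.dopu_low) & anterior
    if focus_exclusion is not None:
        # dilate by the kernel half-extents (x, z within B-scan) so the low-DOPU
        # halo the kernel smears around a focus is never counted as a mass
        struct = np.zeros((3, 1, 3), dtype=bool)
        struct[:, 0, :] = True
        cand &= ~ndimage.binary_dilation(focus_exclusion, structure=struct)
    labels, n = ndimage.label(cand, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return []
    sizes = np.bincount(labels.ravel())
    footprints = []
    for lab in range(1, n + 1):
        if sizes[lab] >= thresholds.mass_min_voxels:
            footprints.append((labels == lab).any(axis=2))
    return footprints


def classify_focus(
    obs: FocusObservation,
    thresholds: ClassificationThresholds,
    mass_footprints: list[np.ndarray] | None = None,
    dopu: DopuVolume | None = None,
    segmentation: SegmentationLine | None = None,
    focus_exclusion: np.ndarray | None = None,
) -> FocusObservation:
    """Apply the exclusion clause and the four-modality concordance rule.

    A focus is excluded when a qualifying low-DOPU mass overlaps its (x, b)
    footprint column; otherwise it is labeled migration iff the minimum DOPU
    is below dopu_low AND all three en-face z-scores meet their thresholds.
    ``mass_footprints`` may be precomputed once per eye with
    :func:`detect_low_dopu_masses`; otherwise dopu and segmentation are needed.
    """
    if mass_footprints is None:
        if dopu is None or segmentation is None:
            mass_footprints = []
        else:
            mass_footprints = detect_low_dopu_masses(
                dopu, segmentation, thresholds, focus_exclusion
            )
    dx, db = thresholds.mass_overlap_dilation_px
    fp_dil = ndimage.binary_dilation(
        obs.footprint, structure=np.ones((2 * dx + 1, 2 * db + 1), dtype=bool))
    excluded = any((fp & fp_dil).any() for fp in mass_footprints)
    if excluded:
        return replace(obs, excluded_mass=True, label="excluded")
    passes = (
        (not math.isnan(obs.min_dopu))
        and obs.min_dopu < thresholds.dopu_low
        and obs.psslo_z >= thresholds.psslo_z
        and obs.nir_z >= thresholds.af_z
        and obs.sw_z >= thresholds.af_z
    )
    return replace(obs, excluded_mass=False,
                   label="migration" if passes else "no_migration")


def classify_eye(
    eye_id: str,
    group: str,
    foci: list[FocusObservation],
    hrf_volume_mm3: float = 0.0,
    ped_volume_mm3: float = math.nan,
) -> EyeRecord:
    """Eye-level tally with migration precedence (an eye with any migrating
    focus counts only in the migration column); excluded foci are ignored."""
    labels = [f.label for f in foci]
    if any(lab is None for lab in labels):
        raise ValueError("all foci must be classified before the eye tally")
    has_mig = any(lab == "migration" for lab in labels)
    has_non = (not has_mig) and any(lab == "no_migration" for lab in labels)
    return EyeRecord(
        eye_id=eye_id,
        group=group,
        has_migrating_hrf=has_mig,
        has_nonmigrating_hrf=has_non,
        hrf_volume_mm3=hrf_volume_mm3,
        ped_volume_mm3=ped_volume_mm3,
        n_foci=len(foci),
        n_excluded=sum(lab == "excluded" for lab in labels),
    )


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e) from the rating contingency.

    When both raters are constant and identical (p_e = 1) kappa is defined
    as 1.0.
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise ValueError("rating lists must have equal length")
    if len(a) == 0:
        raise ValueError("rating lists must be non-empty")
    cats = sorted(set(a) | set(b), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)), dtype=float)
    for ra, rb in zip(a, b):
        table[idx[ra], idx[rb]] += 1
    n = table.sum()
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if abs(1.0 - p_e) < 1e-15:
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))
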