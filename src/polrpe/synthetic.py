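"""Synthetic co-registered PS-OCT / PS-SLO / autofluorescence eye datasets.

The generator emulates the statistical structure the analysis assumes, not
wave optics:

* a retinal slab above an RPE monolayer whose anterior boundary can be raised
  into a drusenoid or serous PED dome (elliptical Gaussian elevation with an
  analytically known volume);
* fully developed speckle: polarization-preserving voxels carry a complex
  circular-Gaussian scalar amplitude on a fixed Jones vector (constant
  normalized Stokes direction), while depolarizing voxels (RPE band, choroid,
  melanin-bearing foci and exudate masses) carry two independent circular-
  Gaussian channels, whose normalized Stokes directions are uniform on the
  Poincare sphere;
* additive circular-Gaussian detector noise per channel on every voxel;
* intraretinal hyperreflective foci with independent melanin / lipofuscin /
  melanolipofuscin content flags; the ground-truth migration label is
  (melanin AND lipofuscin) OR melanolipofuscin;
* crossed-detector PS-SLO frames over input polarization angles
  (angle-independent depolarized floor + sinusoidal crosstalk of period pi)
  and 8-bit NIR-AF / SW-AF images with Gaussian blobs wherever the focus
  pigment flags call for them -- all sharing the PS-OCT (x, b) grid, i.e.
  pre-registered by construction.

All randomness flows through numpy Generators seeded from the given seed, so
identical seeds give bitwise-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erf

from .enface import SegmentationLine
from .params import GROUPS, OpticParams
from .polarimetry import FieldVolume, _crandn
from .psslo import PssloStack


@dataclass(frozen=True)
class PhantomConfig:
    """Tissue reflectivities and modality contrast parameters.

    Reflectivities are mean speckle energies in arbitrary intensity units
    (retina = 1); the instrument does not pin the reflectivity of foci
    relative to the RPE, so the focus gain is a free contrast parameter.
    """

    retina_reflectivity: float = 1.0
    rpe_reflectivity: float = 4.0
    choroid_reflectivity: float = 1.5
    rpe_band_voxels: int = 3
    retina_thickness_um: float = 120.0
    rpe_base_frac: float = 0.68
    min_vitreous_voxels: int = 6
    mass_gain: float = 2.5
    # autofluorescence rendering
    af_background: float = 60.0
    af_amplitude: float = 70.0
    af_noise_sigma: float = 3.0
    # PS-SLO rendering
    slo_floor_base: float = 4.0
    slo_depol_per_voxel: float = 1.5
    slo_crosstalk_amplitude: float = 20.0
    slo_crosstalk_offset: float = 1.0
    slo_noise_sigma: float = 0.5
    slo_uncrossed_level: float = 200.0


@dataclass(frozen=True)
class FocusSpec:
    """One hyperreflective focus (ellipsoid in physical micrometres)."""

    center: tuple[int, int, int]  # (x, b, z) voxel indices
    radius_um: float
    reflectivity_gain: float = 3.0
    melanin: bool = False
    lipofuscin: bool = False
    melanolipofuscin: bool = False

    @property
    def migration_truth(self) -> bool:
        return (self.melanin and self.lipofuscin) or self.melanolipofuscin

    @property
    def depolarizing(self) -> bool:
        return self.melanin or self.melanolipofuscin


@dataclass(frozen=True)
class PedDome:
    """Elliptical Gaussian RPE elevation: height * exp(-dx^2/2sx^2 - db^2/2sb^2)."""

    center_x: int
    center_b: int
    sigma_x_um: float
    sigma_b_um: float
    height_um: float


@dataclass(frozen=True)
class ExudateMass:
    """Cylinder of congested depolarizing HRF (the hard-exudate signature)."""

    center_x: int
    center_b: int
    radius_um: float
    z_top: int
    z_bottom: int  # exclusive


@dataclass(frozen=True)
class GroupConfig:
    ped_kind: str = "none"  # none | drusenoid | serous
    dome_height_um: tuple[float, float] = (0.0, 0.0)
    dome_sigma_um: tuple[float, float] = (0.0, 0.0)
    foci_rate: float = 1.0  # Poisson mean (ignored for serous coupling)
    min_foci: int = 0
    p_migration: float = 0.5
    focus_radius_um: tuple[float, float] = (30.0, 45.0)
    focus_gain: float = 3.0
    #: couple focus count and size to the dome height (mechanical-stress model
    #: of RPE shedding from the PED apex): rate = h/30, radius ~ U(h/4, h/4+12)
    couple_to_dome: bool = False


#: Per-group phantom distributions, shaped to mirror the published per-group
#: migration frequencies; the serous group couples its focus load to the dome
#: height so that HRF volume correlates positively with PED volume.
GROUP_CONFIGS: dict[str, GroupConfig] = {
    "early_intermediate": GroupConfig(foci_rate=0.8, p_migration=0.6),
    "drusenoid_ped": GroupConfig(
        ped_kind="drusenoid", dome_height_um=(35.0, 70.0),
        dome_sigma_um=(250.0, 400.0), foci_rate=1.5, p_migration=0.8),
    "serous_ped": GroupConfig(
        ped_kind="serous", dome_height_um=(70.0, 130.0),
        dome_sigma_um=(375.0, 525.0), foci_rate=2.5, min_foci=1,
        p_migration=0.95, couple_to_dome=True),
    "remission": GroupConfig(foci_rate=1.2, p_migration=0.15),
    "fibrosis": GroupConfig(foci_rate=1.0, p_migration=0.07),
    "geographic_atrophy": GroupConfig(foci_rate=0.5, p_migration=0.7),
}


@dataclass
class RetinaPhantom:
    """Geometric ground truth of one synthetic eye."""

    params: OpticParams
    group: str
    config: PhantomConfig
    rpe_base_depth: int
    rpe_depth_map: np.ndarray  # (x, b) int, anterior RPE boundary
    retina_top: np.ndarray  # (x, b) int, inner retinal surface
    ped_kind: str = "none"
    ped_dome: PedDome | None = None
    foci: list[FocusSpec] = field(default_factory=list)
    exudate_masses: list[ExudateMass] = field(default_factory=list)

    def focus_voxels(self, focus: FocusSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel index arrays (x, b, z) of the focus ellipsoid."""
        p = self.params
        cx, cb, cz = focus.center
        r = focus.radius_um
        ex = int(math.ceil(r / p.pitch_x))
        eb = int(math.ceil(r / p.pitch_b))
        ez = int(math.ceil(r / p.pitch_z))
        xs = np.arange(max(cx - ex, 0), min(cx + ex + 1, p.n_alines))
        bs = np.arange(max(cb - eb, 0), min(cb + eb + 1, p.n_bscans))
        zs = np.arange(max(cz - ez, 0), min(cz + ez + 1, p.n_depth))
        X, B, Z = np.meshgrid(xs, bs, zs, indexing="ij")
        d2 = (((X - cx) * p.pitch_x) ** 2 + ((B - cb) * p.pitch_b) ** 2
              + ((Z - cz) * p.pitch_z) ** 2)
        inside = d2 <= r ** 2
        return X[inside], B[inside], Z[inside]

    def focus_union_mask(self) -> np.ndarray:
        mask = np.zeros(self.params.shape, dtype=bool)
        for f in self.foci:
            xs, bs, zs = self.focus_voxels(f)
            mask[xs, bs, zs] = True
        return mask

    def mass_voxels(self, mass: ExudateMass) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p = self.params
        ex = int(math.ceil(mass.radius_um / p.pitch_x))
        eb = int(math.ceil(mass.radius_um / p.pitch_b))
        xs = np.arange(max(mass.center_x - ex, 0), min(mass.center_x + ex + 1, p.n_alines))
        bs = np.arange(max(mass.center_b - eb, 0), min(mass.center_b + eb + 1, p.n_bscans))
        X, B = np.meshgrid(xs, bs, indexing="ij")
        inside = (((X - mass.center_x) * p.pitch_x) ** 2
                  + ((B - mass.center_b) * p.pitch_b) ** 2) <= mass.radius_um ** 2
        zs = np.arange(max(mass.z_top, 0), min(mass.z_bottom, p.n_depth))
        Xi, Bi = X[inside], B[inside]
        Xr = np.repeat(Xi, len(zs))
        Br = np.repeat(Bi, len(zs))
        Zr = np.tile(zs, len(Xi))
        return Xr, Br, Zr

    def render_maps(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-voxel mean reflectivity and depolarization flag."""
        p, c = self.params, self.config
        refl = np.zeros(p.shape, dtype=float)
        depol = np.zeros(p.shape, dtype=bool)
        zidx = np.arange(p.n_depth)[None, None, :]
        rpe = self.rpe_depth_map[:, :, None]
        top = self.retina_top[:, :, None]
        retina = (zidx >= top) & (zidx < rpe)
        refl[retina] = c.retina_reflectivity
        band = (zidx >= rpe) & (zidx < rpe + c.rpe_band_voxels)
        refl[band] = c.rpe_reflectivity
        depol |= band
        choroid = zidx >= rpe + c.rpe_band_voxels
        refl[choroid] = c.choroid_reflectivity
        depol |= choroid
        for mass in self.exudate_masses:
            xs, bs, zs = self.mass_voxels(mass)
            refl[xs, bs, zs] = c.retina_reflectivity * c.mass_gain
            depol[xs, bs, zs] = True
        for f in self.foci:
            xs, bs, zs = self.focus_voxels(f)
            refl[xs, bs, zs] = c.retina_reflectivity * f.reflectivity_gain
            depol[xs, bs, zs] = f.depolarizing
        return refl, depol

    def analytic_ped_volume_mm3(self) -> float:
        """Integral of the Gaussian dome over the scanned region, in mm^3.

        Uses the error function over the actual lateral footprint, so lateral
        truncation by the scan window is accounted for exactly.
        """
        if self.ped_dome is None:
            return 0.0
        d, p = self.ped_dome, self.params

        def _span(n, pitch, center, sigma):
            lo, hi = -0.5 * pitch, (n - 0.5) * pitch
            c = center * pitch
            s = sigma * math.sqrt(2.0)
            return sigma * math.sqrt(math.pi / 2.0) * (
                erf((hi - c) / s) - erf((lo - c) / s))

        vol_um3 = d.height_um * _span(p.n_alines, p.pitch_x, d.center_x, d.sigma_x_um) \
            * _span(p.n_bscans, p.pitch_b, d.center_b, d.sigma_b_um)
        return vol_um3 * 1e-9

    def discrete_ped_volume_mm3(self) -> float:
        """Volume of the voxelized dome actually present in the phantom."""
        p = self.params
        elev = np.clip(self.rpe_base_depth - self.rpe_depth_map, 0, None)
        return float(elev.sum()) * p.pitch_z * p.pitch_x * p.pitch_b * 1e-9

    def validate(self) -> None:
        p = self.params
        if self.rpe_depth_map.min() < 1 or self.rpe_depth_map.max() > p.n_depth - 2:
            raise ValueError("RPE boundary out of range [1, n_depth-2]")
        for f in self.foci:
            xs, bs, zs = self.focus_voxels(f)
            if (zs >= self.rpe_depth_map[xs, bs]).any():
                raise ValueError("focus extends to or below the RPE boundary")


def _dome_elevation_voxels(dome: PedDome, params: OpticParams) -> np.ndarray:
    x_um = (np.arange(params.n_alines) - dome.center_x) * params.pitch_x
    b_um = (np.arange(params.n_bscans) - dome.center_b) * params.pitch_b
    elev = dome.height_um * np.exp(
        -(x_um[:, None] ** 2) / (2.0 * dome.sigma_x_um ** 2)
        - (b_um[None, :] ** 2) / (2.0 * dome.sigma_b_um ** 2))
    return np.rint(elev / params.pitch_z).astype(int)


def _draw_focus_flags(rng: np.random.Generator, migrating: bool) -> dict:
    if migrating:
        if rng.random() < 0.5:
            return dict(melanin=False, lipofuscin=False, melanolipofuscin=True)
        return dict(melanin=True, lipofuscin=True, melanolipofuscin=False)
    kind = rng.choice(["melanin", "lipofuscin", "plain"])
    return dict(melanin=kind == "melanin", lipofuscin=kind == "lipofuscin",
                melanolipofuscin=False)


def build_phantom(
    params: OpticParams,
    group: str,
    seed: int | np.random.SeedSequence = 0,
    config: PhantomConfig | None = None,
    group_config: GroupConfig | None = None,
) -> RetinaPhantom:
    """Draw one eye's geometry from the per-group distributions.

    Fully reproducible given the seed.  Serous and drusenoid groups receive a
    PED dome; focus counts and pigment flags follow per-group probabilities.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}; expected one of {GROUPS}")
    config = config or PhantomConfig()
    gc = group_config or GROUP_CONFIGS[group]
    rng = np.random.default_rng(seed)
    p = params

    rpe_base = int(round(config.rpe_base_frac * p.n_depth))
    rpe_base = min(max(rpe_base, 2), p.n_depth - 2)
    t_ret = max(int(round(config.retina_thickness_um / p.pitch_z)), 4)
    t_ret = min(t_ret, rpe_base - config.min_vitreous_voxels - 1)

    rpe_map = np.full((p.n_alines, p.n_bscans), rpe_base, dtype=int)
    dome = None
    if gc.ped_kind != "none":
        h = float(rng.uniform(*gc.dome_height_um))
        sx = float(rng.uniform(*gc.dome_sigma_um))
        sb = float(rng.uniform(*gc.dome_sigma_um))
        cx = int(rng.integers(p.n_alines // 3, 2 * p.n_alines // 3 + 1))
        cb = int(rng.integers(p.n_bscans // 3, 2 * p.n_bscans // 3 + 1))
        dome = PedDome(center_x=cx, center_b=cb, sigma_x_um=sx,
                       sigma_b_um=sb, height_um=h)
        elev = _dome_elevation_voxels(dome, p)
        max_elev = rpe_base - t_ret - config.min_vitreous_voxels
        rpe_map = rpe_base - np.minimum(elev, max_elev)
    rpe_map = np.clip(rpe_map, 1, p.n_depth - 2)
    retina_top = np.clip(rpe_map - t_ret, 1, None)

    # focus count and size: Poisson rate, optionally coupled to dome height
    radius_range = gc.focus_radius_um
    if gc.couple_to_dome and dome is not None:
        rate = dome.height_um / 30.0
        radius_range = (0.25 * dome.height_um, 0.25 * dome.height_um + 12.0)
    else:
        rate = gc.foci_rate
    n_foci = max(int(rng.poisson(rate)), gc.min_foci)

    foci: list[FocusSpec] = []
    placed_centers: list[tuple[int, int, float]] = []
    margin_x = min(max(int(200.0 / p.pitch_x), 2), max(p.n_alines // 4, 2))
    margin_b = min(max(int(200.0 / p.pitch_b), 2), max(p.n_bscans // 4, 2))
    for _ in range(n_foci):
        migrating = bool(rng.random() < gc.p_migration)
        flags = _draw_focus_flags(rng, migrating)
        radius = float(rng.uniform(*radius_range))
        ez = int(math.ceil(radius / p.pitch_z))
        for _attempt in range(40):
            cx = int(rng.integers(margin_x, p.n_alines - margin_x))
            cb = int(rng.integers(margin_b, p.n_bscans - margin_b))
            ex = int(math.ceil(radius / p.pitch_x))
            eb = int(math.ceil(radius / p.pitch_b))
            local_rpe = int(rpe_map[max(cx - ex, 0):cx + ex + 1,
                                    max(cb - eb, 0):cb + eb + 1].min())
            local_top = int(retina_top[max(cx - ex, 0):cx + ex + 1,
                                       max(cb - eb, 0):cb + eb + 1].max())
            z_lo = local_top + ez + 2
            z_hi = local_rpe - ez - 2
            if z_lo > z_hi:
                continue
            sep_ok = all(
                math.hypot((cx - ox) * p.pitch_x, (cb - ob) * p.pitch_b)
                >= radius + orad + 60.0
                for ox, ob, orad in placed_centers)
            if not sep_ok:
                continue
            cz = int(rng.integers(z_lo, z_hi + 1))
            foci.append(FocusSpec(center=(cx, cb, cz), radius_um=radius,
                                  reflectivity_gain=gc.focus_gain, **flags))
            placed_centers.append((cx, cb, radius))
            break

    phantom = RetinaPhantom(
        params=p, group=group, config=config, rpe_base_depth=rpe_base,
        rpe_depth_map=rpe_map, retina_top=retina_top,
        ped_kind=gc.ped_kind, ped_dome=dome, foci=foci)
    phantom.validate()
    return phantom


def simulate_psoct_volume(
    phantom: RetinaPhantom,
    params: OpticParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    speckle: bool = True,
) -> FieldVolume:
    """Render the phantom into two-channel complex fields with repeats.

    speckle=True (default) draws fully developed speckle: circular-Gaussian
    amplitudes, independent across repeats.  speckle=False is an idealized
    mode for validation: per-voxel energy equals the mean reflectivity
    exactly, while depolarizing voxels still carry a random Stokes direction.
    Additive circular-Gaussian detector noise with the configured per-channel
    mean energies is applied to every voxel in both modes.
    """
    p = params or phantom.params
    if p.shape != phantom.params.shape:
        raise ValueError("params grid does not match the phantom")
    rng = np.random.default_rng(seed)
    refl, depol = phantom.render_maps()
    shape = (p.n_repeats,) + p.shape
    amp = np.sqrt(refl)[None, :, :, :]

    if speckle:
        a = _crandn(rng, shape, 1.0) * amp
        e1 = a / math.sqrt(2.0)
        e2 = a / math.sqrt(2.0)
        g1 = _crandn(rng, shape, 0.5) * amp
        g2 = _crandn(rng, shape, 0.5) * amp
    else:
        base = np.broadcast_to(amp / math.sqrt(2.0), shape).astype(complex)
        e1 = base
        e2 = base
        u1 = _crandn(rng, shape, 1.0)
        u2 = _crandn(rng, shape, 1.0)
        norm = np.sqrt(np.abs(u1) ** 2 + np.abs(u2) ** 2)
        norm = np.where(norm > 0, norm, 1.0)
        g1 = u1 / norm * amp
        g2 = u2 / norm * amp

    d = depol[None, :, :, :]
    e1 = np.where(d, g1, e1)
    e2 = np.where(d, g2, e2)
    if p.noise_energy_ch1 > 0:
        e1 = e1 + _crandn(rng, shape, p.noise_energy_ch1)
    if p.noise_energy_ch2 > 0:
        e2 = e2 + _crandn(rng, shape, p.noise_energy_ch2)
    return FieldVolume(e1=e1, e2=e2)


def simulate_af_images(
    phantom: RetinaPhantom,
    params: OpticParams | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """8-bit NIR-AF and SW-AF en-face images.

    A Gaussian blob is added over each focus footprint: in NIR-AF iff the
    focus carries melanin or melanolipofuscin, in SW-AF iff it carries
    lipofuscin or melanolipofuscin.
    """
    p = params or phantom.params
    c = phantom.config
    rng = np.random.default_rng(seed)
    x_um = np.arange(p.n_alines)[:, None] * p.pitch_x
    b_um = np.arange(p.n_bscans)[None, :] * p.pitch_b

    def _render(flag_fn) -> np.ndarray:
        img = np.full((p.n_alines, p.n_bscans), c.af_background, dtype=float)
        for f in phantom.foci:
            if not flag_fn(f):
                continue
            cx, cb, _ = f.center
            d2 = ((x_um - cx * p.pitch_x) ** 2 + (b_um - cb * p.pitch_b) ** 2)
            img += c.af_amplitude * np.exp(-d2 / (2.0 * f.radius_um ** 2))
        img += rng.normal(0.0, c.af_noise_sigma, size=img.shape)
        return np.clip(np.round(img), 0, 255).astype(np.uint8)

    nir = _render(lambda f: f.melanin or f.melanolipofuscin)
    sw = _render(lambda f: f.lipofuscin or f.melanolipofuscin)
    return nir, sw


def simulate_psslo_stack(
    phantom: RetinaPhantom,
    params: OpticParams | None = None,
    n_angles: int = 8,
    seed: int | np.random.SeedSequence = 0,
    phase: str | float = "random",
    noise: bool = True,
) -> PssloStack:
    """Crossed-detector frame stack over input polarization angles.

    Each frame is an angle-independent floor contributed by the depolarizing
    intraretinal structures in the column (the uniform RPE/choroid return is
    folded into the base level), plus a sinusoidal crosstalk term of period pi
    from the polarization-preserving tissue, plus optional detector noise.
    The per-pixel minimum over angles therefore isolates the depolarized
    contribution up to noise.
    """
    if n_angles < 2:
        raise ValueError("n_angles must be >= 2")
    p = params or phantom.params
    c = phantom.config
    rng = np.random.default_rng(seed)

    depol_count = np.zeros((p.n_alines, p.n_bscans), dtype=float)
    for f in phantom.foci:
        if f.depolarizing:
            xs, bs, _ = phantom.focus_voxels(f)
            np.add.at(depol_count, (xs, bs), 1.0)
    for m in phantom.exudate_masses:
        xs, bs, _ = phantom.mass_voxels(m)
        np.add.at(depol_count, (xs, bs), 1.0)

    floor = c.slo_floor_base + c.slo_depol_per_voxel * depol_count
    if phase == "random":
        phi = rng.uniform(0.0, math.pi, size=floor.shape)
    else:
        phi = np.full(floor.shape, float(phase))
    angles = np.linspace(0.0, math.pi, n_angles, endpoint=False)
    cross = (c.slo_crosstalk_offset + 0.5 * c.slo_crosstalk_amplitude
             * (1.0 - np.cos(2.0 * angles[:, None, None] - 2.0 * phi[None])))
    frames = floor[None] + cross
    uncrossed = c.slo_uncrossed_level - cross
    if noise and c.slo_noise_sigma > 0:
        frames = frames + rng.normal(0.0, c.slo_noise_sigma, size=frames.shape)
        uncrossed = uncrossed + rng.normal(0.0, c.slo_noise_sigma, size=frames.shape)
    return PssloStack(frames=frames, angles=angles, uncrossed=uncrossed)


@dataclass
class FocusTruth:
    spec: FocusSpec
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]
    migration: bool


@dataclass
class EyeTruth:
    """Ground truth labels and volumes of one synthetic eye."""

    foci: list[FocusTruth]
    rpe_base_depth: int
    ped_kind: str
    ped_volume_mm3: float  # voxelized dome volume actually present
    ped_volume_analytic_mm3: float
    hrf_voxel_count: int

    def focus_union_mask(self, shape) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        for ft in self.foci:
            xs, bs, zs = ft.voxels
            mask[xs, bs, zs] = True
        return mask


@dataclass
class SyntheticEyeDataset:
    """All modalities of one synthetic eye on a shared (x, b) grid."""

    eye_id: str
    group: str
    params: OpticParams
    phantom: RetinaPhantom
    fields: FieldVolume
    psslo: PssloStack
    nir_af: np.ndarray
    sw_af: np.ndarray
    segmentation: SegmentationLine
    truth: EyeTruth
    vitreous_max_z: int


def simulate_eye(
    phantom: RetinaPhantom,
    seed: int | np.random.SeedSequence = 0,
    eye_id: str = "eye0",
    n_psslo_angles: int = 8,
    speckle: bool = True,
) -> SyntheticEyeDataset:
    """Render one phantom into the full multimodal dataset."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_oct, s_af, s_slo = ss.spawn(3)
    p = phantom.params
    fields = simulate_psoct_volume(phantom, p, seed=s_oct, speckle=speckle)
    nir, sw = simulate_af_images(phantom, p, seed=s_af)
    stack = simulate_psslo_stack(phantom, p, n_angles=n_psslo_angles, seed=s_slo)
    foci_truth = [
        FocusTruth(spec=f, voxels=phantom.focus_voxels(f), migration=f.migration_truth)
        for f in phantom.foci
    ]
    truth = EyeTruth(
        foci=foci_truth,
        rpe_base_depth=phantom.rpe_base_depth,
        ped_kind=phantom.ped_kind,
        ped_volume_mm3=phantom.discrete_ped_volume_mm3(),
        ped_volume_analytic_mm3=phantom.analytic_ped_volume_mm3(),
        hrf_voxel_count=int(sum(len(ft.voxels[0]) for ft in foci_truth)),
    )
    vitreous_max_z = max(int(phantom.retina_top.min()) - 2, 1)
    return SyntheticEyeDataset(
        eye_id=eye_id, group=phantom.group, params=p, phantom=phantom,
        fields=fields, psslo=stack, nir_af=nir, sw_af=sw,
        segmentation=SegmentationLine(line=phantom.rpe_depth_map, provenance="truth"),
        truth=truth, vitreous_max_z=vitreous_max_z)


def iter_cohort(
    cohort_spec: dict[str, int],
    params: OpticParams | None = None,
    seed: int = 0,
    config: PhantomConfig | None = None,
    n_psslo_angles: int = 8,
    speckle: bool = True,
):
    """Yield synthetic eyes one at a time (memory-friendly form of
    :func:`generate_cohort`); per-eye seeds derive from the master seed."""
    params = params or OpticParams()
    for g, n in cohort_spec.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group label {g!r}; expected one of {GROUPS}")
        if n < 0:
            raise ValueError("eye counts must be >= 0")
    total = sum(cohort_spec.values())
    master = np.random.SeedSequence(seed)
    children = master.spawn(total)
    i = 0
    for g in [g for g in GROUPS if cohort_spec.get(g, 0) > 0]:
        for _ in range(cohort_spec[g]):
            s_ph, s_eye = children[i].spawn(2)
            phantom = build_phantom(params, g, seed=s_ph, config=config)
            yield simulate_eye(phantom, seed=s_eye, eye_id=f"eye{i:03d}",
                               n_psslo_angles=n_psslo_angles, speckle=speckle)
            i += 1


def generate_cohort(
    cohort_spec: dict[str, int],
    params: OpticParams | None = None,
    seed: int = 0,
    **kwargs,
) -> list[SyntheticEyeDataset]:
    """Reproducible list of synthetic eyes per the group counts."""
    return list(iter_cohort(cohort_spec, params=params, seed=seed, **kwargs))


def cohort_truth_table(datasets) -> pd.DataFrame:
    """One row per focus (plus one per focus-free eye) with ground truth."""
    rows = []
    for ds in datasets:
        if not ds.truth.foci:
            rows.append({"eye_id": ds.eye_id, "group": ds.group, "focus_id": -1,
                         "x": -1, "b": -1, "z": -1, "radius_um": 0.0,
                         "melanin": False, "lipofuscin": False,
                         "melanolipofuscin": False, "migration_truth": False,
                         "ped_kind": ds.truth.ped_kind,
                         "ped_volume_mm3": ds.truth.ped_volume_mm3})
        for i, ft in enumerate(ds.truth.foci):
            f = ft.spec
            rows.append({"eye_id": ds.eye_id, "group": ds.group, "focus_id": i,
                         "x": f.center[0], "b": f.center[1], "z": f.center[2],
                         "radius_um": f.radius_um, "melanin": f.melanin,
                         "lipofuscin": f.lipofuscin,
                         "melanolipofuscin": f.melanolipofuscin,
                         "migration_truth": ft.migration,
                         "ped_kind": ds.truth.ped_kind,
                         "ped_volume_mm3": ds.truth.ped_volume_mm3})
    return pd.DataFrame(rows)


def add_exudate_mass(
    phantom: RetinaPhantom,
    center_x: int,
    center_b: int,
    radius_um: float = 180.0,
    thickness_voxels: int = 8,
    z_bottom_offset: int = 6,
) -> RetinaPhantom:
    """Return a copy of the phantom with a depolarizing exudate mass whose
    column overlaps (center_x, center_b), placed in the retina above the RPE."""
    z_bottom = int(phantom.rpe_depth_map[center_x, center_b]) - z_bottom_offset
    z_top = max(z_bottom - thickness_voxels, int(phantom.retina_top[center_x, center_b]) + 1)
    if z_top >= z_bottom:
        raise ValueError("no room for an exudate mass above the RPE here")
    mass = ExudateMass(center_x=center_x, center_b=center_b,
                       radius_um=radius_um, z_top=z_top, z_bottom=z_bottom)
    return replace(phantom, exudate_masses=phantom.exudate_masses + [mass])
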