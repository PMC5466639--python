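"""Scan geometry, voxel pitches and study-group labels.

The nominal raster protocol is 512 A-lines x 256 B-scans over a 6.0 x 6.0 mm
macular region with four repeated B-scans per location.  Voxel pitches default
to the printed values 11.7 x 23.5 x 3.6 um; note that 6.0 mm / 512 = 11.72 um,
but the pitches are stored independently of the grid counts because all volume
arithmetic must use the printed pitch values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

#: The six AMD study groups.
GROUPS = (
    "early_intermediate",
    "drusenoid_ped",
    "serous_ped",
    "remission",
    "fibrosis",
    "geographic_atrophy",
)


@dataclass(frozen=True)
class OpticParams:
    """Scan grid, voxel pitches and detector noise energies.

    Parameters
    ----------
    n_alines, n_bscans, n_depth : int
        Grid counts along the fast transverse (x), slow transverse (b) and
        depth (z) axes.  Depth defaults to a desk-scale 128 (configurable up
        to the instrument's 583-pixel range).
    n_repeats : int
        Number of repeated B-scan acquisitions per location (default 4).
    pitch_x, pitch_b, pitch_z : float
        Voxel pitches in micrometres (defaults 11.7, 23.5, 3.6).
    noise_energy_ch1, noise_energy_ch2 : float
        Mean additive detector-noise energy per polarization channel, in the
        same arbitrary intensity units as the field energy.
    """

    n_alines: int = 512
    n_bscans: int = 256
    n_depth: int = 128
    n_repeats: int = 4
    pitch_x: float = 11.7
    pitch_b: float = 23.5
    pitch_z: float = 3.6
    noise_energy_ch1: float = 0.05
    noise_energy_ch2: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_alines", "n_bscans", "n_depth", "n_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("pitch_x", "pitch_b", "pitch_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("noise_energy_ch1", "noise_energy_ch2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Volume shape as (x, b, z)."""
        return (self.n_alines, self.n_bscans, self.n_depth)

    @property
    def voxel_volume_um3(self) -> float:
        return self.pitch_x * self.pitch_b * self.pitch_z

    @property
    def fov_mm(self) -> tuple[float, float]:
        """Lateral field of view (x, b) in millimetres."""
        return (self.n_alines * self.pitch_x * 1e-3,
                self.n_bscans * self.pitch_b * 1e-3)

    def with_(self, **kwargs) -> "OpticParams":
        return replace(self, **kwargs)
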