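"""Synthetic OCT-like choroid cohorts with controllable group and depth effects.

The generator emulates the structure of a chorioretinal imaging study: three
groups of eyes (healthy, CSCR, unaffected fellow eyes of CSCR patients), a
stack of b-scans per eye, and en face slices reconstructed at fixed fractions
of normalized choroid depth.

Image model
-----------
Tissue reflectivity is a constant multiplied by gamma-distributed speckle
(shape ``speckle_shape``, mean 1), the standard first-order approximation of
fully developed OCT speckle.  Choroidal vessels appear as dark elliptical
cross-sections with soft edges, placed by a Poisson process over the choroid.
A vessel centred at normalized depth ``d`` has radius::

    vessel_radius_base_px * group_multiplier * (1 + depth_gradient * d)

so ``cscr_radius_multiplier > 1`` creates a group contrast (dilated
pachyvessels) and ``depth_gradient > 0`` makes vessels — and hence the group
contrast in absolute size — grow with depth, mimicking the small-to-large
calibre progression from the choriocapillaris to Haller's layer.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from .roi_model import (
    BoundaryPair,
    CohortDataset,
    EyeRecord,
    Group,
    ImageSample,
    Modality,
    build_enface_stack,
)

__all__ = ["SyntheticConfig", "generate_bscan", "generate_cohort"]


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Cohort-generation parameters.

    Defaults mirror the clinical study design being emulated: 30 healthy,
    39 CSCR, and 20 fellow eyes; 500 b-scans and 100 en face slices per eye.
    ``desk_scale`` returns a small configuration for fast experimentation.
    """

    n_healthy_eyes: int = 30
    n_cscr_eyes: int = 39
    n_fellow_eyes: int = 20
    bscans_per_eye: int = 500
    enface_slices_per_eye: int = 100
    image_height: int = 128
    image_width: int = 512
    base_thickness_px: int = 60
    #: gamma shape of multiplicative speckle; lower = noisier
    speckle_shape: float = 4.0
    #: expected vessels per choroid pixel
    vessel_density: float = 0.002
    vessel_radius_base_px: float = 3.0
    cscr_radius_multiplier: float = 1.5
    fellow_radius_multiplier: float = 1.5
    #: vessel radius scales as (1 + depth_gradient * depth_fraction)
    depth_gradient: float = 1.0
    #: fractional intensity drop inside a vessel, in (0, 1]
    vessel_darkening: float = 0.7
    seed: int = 0
    #: mean tissue reflectivity on the 8-bit scale
    tissue_level: float = 120.0
    #: log-normal sigma of per-eye random effects on thickness, reflectivity,
    #: and vessel density; emulates between-eye biological variability (images
    #: within an eye are correlated, eyes differ)
    eye_sigma: float = 0.25

    def __post_init__(self) -> None:
        if min(self.n_healthy_eyes, self.n_cscr_eyes, self.n_fellow_eyes) < 0:
            raise ConfigError("eye counts must be >= 0")
        if self.cscr_radius_multiplier < 1 or self.fellow_radius_multiplier < 1:
            raise ConfigError("radius multipliers must be >= 1")
        if self.depth_gradient < 0:
            raise ConfigError("depth_gradient must be >= 0")
        if not 0 < self.vessel_darkening <= 1:
            raise ConfigError("vessel_darkening must be in (0, 1]")
        if self.speckle_shape <= 0:
            raise ConfigError("speckle_shape must be positive")
        if self.base_thickness_px < 3:
            raise ConfigError("base_thickness_px below 3 px is degenerate")

    @classmethod
    def desk_scale(cls, **overrides) -> "SyntheticConfig":
        """Small configuration (10 eyes/group, 20 b-scans, 64x256 px) for tests."""
        defaults = dict(
            n_healthy_eyes=10,
            n_cscr_eyes=10,
            n_fellow_eyes=10,
            bscans_per_eye=20,
            enface_slices_per_eye=50,
            image_height=64,
            image_width=256,
            base_thickness_px=40,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def null(cls, **overrides) -> "SyntheticConfig":
        """Desk-scale configuration with no group effect (all multipliers 1, g=0)."""
        defaults = dict(
            cscr_radius_multiplier=1.0, fellow_radius_multiplier=1.0, depth_gradient=0.0
        )
        defaults.update(overrides)
        return cls.desk_scale(**defaults)

    def group_multiplier(self, group: Group) -> float:
        return {
            Group.HEALTHY: 1.0,
            Group.CSCR: self.cscr_radius_multiplier,
            Group.FELLOW: self.fellow_radius_multiplier,
        }[Group(group)]

    def to_dict(self) -> dict:
        return asdict(self)


def _smooth_boundaries(config: SyntheticConfig, rng: np.random.Generator) -> BoundaryPair:
    """Smooth sinusoidal inner boundary + gently varying thickness."""
    w = config.image_width
    c = np.arange(w)
    top = config.image_height * 0.15
    amp = rng.uniform(1.0, 3.0)
    phase = rng.uniform(0, 2 * np.pi)
    inner = top + amp * np.sin(2 * np.pi * c / w + phase)
    thick = config.base_thickness_px * (
        1.0 + 0.05 * np.sin(2 * np.pi * c / w + rng.uniform(0, 2 * np.pi))
    )
    inner = np.clip(np.rint(inner).astype(int), 0, config.image_height - 3)
    outer = np.clip(inner + np.rint(thick).astype(int) - 1, inner, config.image_height - 1)
    if np.any(outer - inner + 1 < 3):
        raise ConfigError("choroid thinner than 3 px; increase base_thickness_px")
    return BoundaryPair(inner=inner, outer=outer)


def _vessel_coverage(
    shape: tuple[int, int],
    boundaries: BoundaryPair,
    config: SyntheticConfig,
    multiplier: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Soft [0, 1] occupancy map of dark vessel cross-sections."""
    h, w = shape
    cover = np.zeros(shape)
    area = float(boundaries.thickness.sum())
    n_vessels = rng.poisson(config.vessel_density * area)
    edge = 0.25  # soft-edge half-width, in units of normalized radius
    aspect = 1.5  # vessels wider than tall
    for _ in range(n_vessels):
        col = rng.uniform(0, w)
        d = rng.uniform(0, 1)  # normalized depth of vessel centre
        c0 = int(np.clip(col, 0, w - 1))
        if not boundaries.valid_columns[c0]:
            continue
        row = boundaries.inner[c0] + d * (boundaries.thickness[c0] - 1)
        radius = config.vessel_radius_base_px * multiplier * (1 + config.depth_gradient * d)
        rx, ry = radius * aspect, radius
        r_lo = max(0, int(row - ry * (1 + edge)) - 1)
        r_hi = min(h, int(row + ry * (1 + edge)) + 2)
        c_lo = max(0, int(col - rx * (1 + edge)) - 1)
        c_hi = min(w, int(col + rx * (1 + edge)) + 2)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
        rho = np.sqrt(((rr - row) / ry) ** 2 + ((cc - col) / rx) ** 2)
        patch = np.clip(((1 + edge) - rho) / (2 * edge), 0.0, 1.0)
        np.maximum(cover[r_lo:r_hi, c_lo:c_hi], patch, out=cover[r_lo:r_hi, c_lo:c_hi])
    return cover


def generate_bscan(
    config: SyntheticConfig,
    group: Group | str,
    rng: np.random.Generator,
    eye_id: str = "eye",
    patient_id: str = "pat",
    slice_index: int = 0,
) -> tuple[ImageSample, BoundaryPair]:
    """Generate one synthetic b-scan and its choroid boundary pair."""
    group = Group(group)
    boundaries = _smooth_boundaries(config, rng)
    h, w = config.image_height, config.image_width
    speckle = rng.gamma(config.speckle_shape, 1.0 / config.speckle_shape, size=(h, w))
    cover = _vessel_coverage((h, w), boundaries, config, config.group_multiplier(group), rng)
    rows = np.arange(h)[:, None]
    mask = (rows >= boundaries.inner[None, :]) & (rows <= boundaries.outer[None, :])
    mask &= boundaries.valid_columns[None, :]
    level = np.where(mask, config.tissue_level, config.tissue_level * 0.25)
    img = level * speckle * (1.0 - config.vessel_darkening * cover * mask)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    sample = ImageSample(
        image=img,
        mask=mask,
        eye_id=eye_id,
        patient_id=patient_id,
        group=group,
        modality=Modality.HORIZONTAL,
        slice_index=slice_index,
    )
    return sample, boundaries


def generate_cohort(config: SyntheticConfig) -> CohortDataset:
    """Generate a full synthetic cohort, deterministic given ``config.seed``.

    Fellow eyes share a patient with a CSCR eye where possible (the fellow eye
    is the unaffected contralateral eye of a CSCR patient); healthy and CSCR
    eyes otherwise each get their own patient.
    """
    plan: list[tuple[str, str, Group]] = []
    for i in range(config.n_healthy_eyes):
        plan.append((f"H{i:03d}", f"PH{i:03d}", Group.HEALTHY))
    for i in range(config.n_cscr_eyes):
        plan.append((f"C{i:03d}", f"PC{i:03d}", Group.CSCR))
    for i in range(config.n_fellow_eyes):
        pid = f"PC{i:03d}" if i < config.n_cscr_eyes else f"PF{i:03d}"
        plan.append((f"F{i:03d}", pid, Group.FELLOW))

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(plan))
    eyes: list[EyeRecord] = []
    for (eye_id, patient_id, group), child in zip(plan, children):
        rng = np.random.default_rng(child)
        # per-eye random effects: every eye gets its own thickness, mean
        # reflectivity, and vessel density, shared by all of its images
        s = config.eye_sigma
        eye_cfg = replace(
            config,
            base_thickness_px=max(3, int(round(config.base_thickness_px * rng.lognormal(0, s)))),
            tissue_level=config.tissue_level * rng.lognormal(0, s),
            vessel_density=config.vessel_density * rng.lognormal(0, s),
        )
        bscans, boundaries = [], []
        for j in range(config.bscans_per_eye):
            samp, b = generate_bscan(
                eye_cfg, group, rng, eye_id=eye_id, patient_id=patient_id, slice_index=j
            )
            bscans.append(samp)
            boundaries.append(b)
        enface = (
            build_enface_stack(bscans, boundaries, config.enface_slices_per_eye)
            if config.enface_slices_per_eye > 0
            else []
        )
        eyes.append(
            EyeRecord(
                eye_id=eye_id,
                patient_id=patient_id,
                group=group,
                horizontal_samples=bscans,
                enface_samples=enface,
            )
        )
    return CohortDataset(eyes=eyes)
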