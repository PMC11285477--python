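"""Synthetic wear-facet height maps and full study designs.

The generator emulates the two texture regimes seen on carnivoran enamel
facets:

* **attrition** (tooth-on-tooth shear-cutting, e.g. the carnassial P4
  facet 9): a smooth Gaussian background overlaid by dense, near-parallel
  striations following the orthal chewing stroke (orientation ≈ 90°, i.e.
  along +y), with only occasional craters;
* **crushing** (post-carnassial puncture-crushing, e.g. M1/m2): a rougher
  background with a dense field of Gaussian-profile craters from hard-tissue
  impacts and a sparser groove set along the dominant secondary contact
  direction (≈ 30°).

Study generation is hierarchical: population effect multipliers → lognormal
per-specimen random effects → independent scan noise, with 4 scans per facet
per individual.  Every artifact is a pure function of the design and the
master seed (numpy SeedSequence spawning).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .surface_io import HeightMap

#: default scan geometry: 512×512 points over a 160×160 µm field (100× objective)
DEFAULT_SHAPE = (512, 512)
DEFAULT_FIELD_UM = 160.0


@dataclass
class StriationSet:
    """Poisson set of elongated half-cylindrical grooves."""

    rate: float = 0.0  # expected groove count per field
    orientation: float = 90.0  # long-axis direction, ° CCW from +x in [0, 180)
    orientation_sd: float = 4.0  # angular jitter (°)
    width: float = 1.5  # groove width (µm)
    depth: float = 0.25  # median groove depth (µm), lognormal with sigma below
    depth_sigma: float = 0.35  # lognormal shape of the depth distribution


@dataclass
class CraterSet:
    """Poisson set of Gaussian-profile pits."""

    rate: float = 0.0  # expected crater count per field
    radius: float = 2.5  # median crater radius (µm)
    radius_sigma: float = 0.3
    depth: float = 0.8  # median crater depth (µm)
    depth_sigma: float = 0.35


@dataclass
class FacetModel:
    """Generative model of one facet class."""

    facet_class: str  # "attrition" | "crushing"
    sigma_base: float = 0.05  # background roughness SD (µm)
    corr_length: float = 2.0  # background correlation length L (µm)
    striations: StriationSet = field(default_factory=StriationSet)
    craters: CraterSet = field(default_factory=CraterSet)
    form_amplitude: float = 0.0  # optional quadratic form term (µm), exercises the F-operator

    def __post_init__(self):
        if self.sigma_base <= 0 or self.corr_length <= 0:
            raise ValueError("all scales must be positive")
        if not (0.0 <= self.striations.orientation < 180.0):
            raise ValueError("striation orientation must lie in [0°, 180°)")


def attrition_model() -> FacetModel:
    """Default shear-cutting facet: dense orthal striations, few craters."""
    return FacetModel(
        facet_class="attrition",
        sigma_base=0.04,
        corr_length=2.0,
        striations=StriationSet(rate=80.0, orientation=90.0, orientation_sd=4.0,
                                width=1.5, depth=0.25),
        craters=CraterSet(rate=20.0, radius=2.5, depth=0.5),
    )


def crushing_model() -> FacetModel:
    """Default crushing facet: dense crater field plus a 30° groove set."""
    return FacetModel(
        facet_class="crushing",
        sigma_base=0.08,
        corr_length=3.0,
        striations=StriationSet(rate=30.0, orientation=30.0, orientation_sd=6.0,
                                width=2.5, depth=0.5),
        craters=CraterSet(rate=40.0, radius=3.0, depth=1.2),
    )


# ---------------------------------------------------------------------------
# surface primitives
# ---------------------------------------------------------------------------


def gen_background(shape, dx: float, sigma_base: float, corr_length: float, seed) -> HeightMap:
    """Stationary Gaussian random surface with isotropic squared-exponential
    correlation of length L and marginal SD sigma_base.

    Synthesis: periodic Gaussian smoothing of white noise (convolving white
    noise with a Gaussian of σ = L/√2 yields ACF ∝ exp(−r²/(2L²))), then
    rescaling to the target SD.  Fully determined by the seed.
    """
    if corr_length < 2.0 * dx:
        raise ValueError(f"corr_length {corr_length} µm aliases at spacing dx = {dx} µm")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    sig_px = (corr_length / np.sqrt(2.0)) / dx
    z = ndimage.gaussian_filter(white, sigma=sig_px, mode="wrap")
    z -= z.mean()
    sd = z.std()
    if sd > 0:
        z *= sigma_base / sd
    return HeightMap(z, dx=dx, dy=dx, meta={"sigma_base": sigma_base, "corr_length": corr_length})


def add_striations(hm: HeightMap, striations: StriationSet, rng) -> HeightMap:
    """Subtract a Poisson set of half-cylindrical grooves at the set orientation.

    The true orientation and realised count are recorded in ``meta``.
    """
    rng = np.random.default_rng(rng)
    z = hm.heights.copy()
    ny, nx = z.shape
    y, x = np.mgrid[0:ny, 0:nx]
    x = x * hm.dx
    y = y * hm.dy
    n = rng.poisson(striations.rate)
    for _ in range(n):
        theta = np.deg2rad(striations.orientation + striations.orientation_sd * rng.standard_normal())
        x0 = rng.uniform(0, nx * hm.dx)
        y0 = rng.uniform(0, ny * hm.dy)
        depth = striations.depth * rng.lognormal(0.0, striations.depth_sigma)
        half_w = 0.5 * striations.width
        s = -np.sin(theta) * (x - x0) + np.cos(theta) * (y - y0)  # perpendicular distance
        u = 1.0 - (s / half_w) ** 2
        np.subtract(z, depth * np.sqrt(np.maximum(u, 0.0)), out=z)
    return hm.copy_with(
        heights=z,
        striation_orientation=striations.orientation,
        striation_count=int(n),
    )


def add_craters(hm: HeightMap, craters: CraterSet, rng) -> HeightMap:
    """Subtract a Poisson set of Gaussian-profile pits; truth recorded in meta."""
    rng = np.random.default_rng(rng)
    z = hm.heights.copy()
    ny, nx = z.shape
    y, x = np.mgrid[0:ny, 0:nx]
    x = x * hm.dx
    y = y * hm.dy
    n = rng.poisson(craters.rate)
    depths = []
    for _ in range(n):
        x0 = rng.uniform(0, nx * hm.dx)
        y0 = rng.uniform(0, ny * hm.dy)
        radius = craters.radius * rng.lognormal(0.0, craters.radius_sigma)
        depth = craters.depth * rng.lognormal(0.0, craters.depth_sigma)
        depths.append(depth)
        rho2 = (x - x0) ** 2 + (y - y0) ** 2
        np.subtract(z, depth * np.exp(-rho2 / (2.0 * radius**2)), out=z)
    return hm.copy_with(
        heights=z,
        crater_count=int(n),
        crater_mean_depth=float(np.mean(depths)) if depths else 0.0,
        crater_max_depth=float(np.max(depths)) if depths else 0.0,
    )


def make_facet(model: FacetModel, shape=DEFAULT_SHAPE, dx: float | None = None, seed=0) -> HeightMap:
    """Generate one scan of a facet from its model (background + features)."""
    if dx is None:
        dx = DEFAULT_FIELD_UM / shape[1]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_bg, s_str, s_crat = ss.spawn(3)
    hm = gen_background(shape, dx, model.sigma_base, model.corr_length, s_bg)
    if model.form_amplitude:
        ny, nx = shape
        yn, xn = np.mgrid[0:ny, 0:nx]
        xn = xn / (nx - 1) * 2.0 - 1.0
        yn = yn / (ny - 1) * 2.0 - 1.0
        hm = hm.copy_with(heights=hm.heights + model.form_amplitude * (xn**2 + yn**2))
    if model.striations.rate > 0:
        hm = add_striations(hm, model.striations, s_str)
    if model.craters.rate > 0:
        hm = add_craters(hm, model.craters, s_crat)
    hm.meta["facet_class"] = model.facet_class
    return hm


# ---------------------------------------------------------------------------
# study designs
# ---------------------------------------------------------------------------

#: sampled facet per tooth position, as in the wolf study design
TOOTH_FACETS = (("P4", "9", "attrition"), ("M1", "3", "crushing"),
                ("m1", "9", "attrition"), ("m2", "9", "crushing"))


@dataclass
class PopulationEffects:
    """Multiplicative effects a population applies to the facet models."""

    crater_depth: float = 1.0
    crater_rate: float = 1.0
    striation_depth: float = 1.0
    roughness: float = 1.0

    def __post_init__(self):
        for v in (self.crater_depth, self.crater_rate, self.striation_depth, self.roughness):
            if v <= 0:
                raise ValueError("effect multipliers must be positive")


@dataclass
class StudyDesign:
    """Hierarchical design: populations → specimens → facets → scans."""

    populations: dict  # name -> (n_specimens, PopulationEffects)
    teeth: tuple = TOOTH_FACETS
    scans_per_facet: int = 4
    specimen_sigma: float = 0.15  # SD of the lognormal per-specimen effect
    shape: tuple = DEFAULT_SHAPE
    dx: float | None = None
    master_seed: int = 0

    def __post_init__(self):
        if self.scans_per_facet < 1 or not self.populations:
            raise ValueError("counts must be >= 1")


def hypothesis1_design(master_seed: int = 0, shape=(256, 256), scans: int = 4) -> StudyDesign:
    """Two-population design for the prey-size hypothesis: 12 'Sweden'
    specimens with crater depth doubled versus 8 'Alaska' specimens,
    P4 facet 9 only, 4 scans each."""
    return StudyDesign(
        populations={
            "Sweden": (12, PopulationEffects(crater_depth=2.0)),
            "Alaska": (8, PopulationEffects()),
        },
        teeth=(("P4", "9", "attrition"),),
        scans_per_facet=scans,
        shape=shape,
        dx=0.625,
        master_seed=master_seed,
    )


def _scaled_model(base: FacetModel, eff: PopulationEffects, spec_mult: float) -> FacetModel:
    st = replace(base.striations, depth=base.striations.depth * eff.striation_depth * spec_mult)
    cr = replace(
        base.craters,
        depth=base.craters.depth * eff.crater_depth * spec_mult,
        rate=base.craters.rate * eff.crater_rate,
    )
    return replace(base, sigma_base=base.sigma_base * eff.roughness, striations=st, craters=cr)


def gen_study(design: StudyDesign):
    """Generate all scans of a study plus the latent truth table.

    Yields the scans as a list of :class:`HeightMap` (metadata populated with
    specimen/population/sex/tooth/facet/scan) and a DataFrame of the latent
    per-scan generative parameters.  Reproducible: a pure function of the
    design and its master seed.
    """
    ss = np.random.SeedSequence(design.master_seed)
    base_models = {"attrition": attrition_model(), "crushing": crushing_model()}
    maps: list[HeightMap] = []
    truth = []
    spec_idx = 0
    for pop, (n_spec, eff) in design.populations.items():
        pop_ss = ss.spawn(1)[0]
        for k in range(n_spec):
            spec_idx += 1
            spec_id = f"{pop[:3].upper()}{spec_idx:03d}"
            sex = "female" if k % 2 == 0 else "male"
            spec_ss = pop_ss.spawn(1)[0]
            spec_rng = np.random.default_rng(spec_ss)
            spec_mult = float(np.exp(design.specimen_sigma * spec_rng.standard_normal()))
            for tooth, facet, fclass in design.teeth:
                model = _scaled_model(base_models[fclass], eff, spec_mult)
                for scan in range(1, design.scans_per_facet + 1):
                    scan_seed = spec_ss.spawn(1)[0]
                    hm = make_facet(model, shape=design.shape, dx=design.dx, seed=scan_seed)
                    hm.meta.update(
                        specimen=spec_id, population=pop, sex=sex, age_class="adult",
                        tooth=tooth, facet=facet, scan=str(scan),
                    )
                    maps.append(hm)
                    truth.append(
                        dict(
                            specimen=spec_id, population=pop, sex=sex, tooth=tooth,
                            facet=facet, scan=scan, facet_class=fclass,
                            specimen_mult=spec_mult,
                            crater_depth=model.craters.depth,
                            crater_rate=model.craters.rate,
                            striation_depth=model.striations.depth,
                            striation_orientation=model.striations.orientation,
                            sigma_base=model.sigma_base,
                            striation_count=hm.meta.get("striation_count", 0),
                            crater_count=hm.meta.get("crater_count", 0),
                        )
                    )
    return maps, pd.DataFrame(truth)
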