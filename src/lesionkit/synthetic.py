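"""Synthetic SUV phantoms and simulated patient cohorts.

Real PET cohorts in this problem area are rarely deposited, so validation
rests on two generators with analytically known ground truth:

* **Phantoms** — SUV volumes containing lesions whose geometry at the 41%
  iso-contour is closed-form: uniform-intensity spheres and ellipsoids
  (any threshold between background and peak recovers the exact shape) and
  Gaussian blobs (the iso-contour at fraction f of the peak is the sphere of
  radius ``r* = sigma * sqrt(2 ln(1/f))``). Truth volumes/surfaces use
  V = 4/3 pi abc and the exact Legendre elliptic-integral ellipsoid surface.

* **Cohorts** — patients with Bernoulli bulky / extra-stage flags, analytic
  sphere lesions consistent with those flags, and proportional-hazards
  survival times drawn by inverse transform
  ``T = -ln(U) / (h0 * exp(b_bulky * x_bulky + b_extra * x_extra))`` with
  uniform censoring.

Random streams are split per purpose (flags, geometry, survival, noise) so
changing the cohort size never perturbs phantom geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .indicators import BULKY_DIAMETER_MM, Compartment, Side, SiteAnnotation, synergy_group
from .volume import SUVVolume

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "CohortSpec",
    "CohortTruth",
    "isocontour_radius",
    "sphere_volume",
    "sphere_surface",
    "ellipsoid_surface",
    "make_phantom",
    "make_cohort",
    "phantom_spec_for_patient",
]

DEFAULT_FRACTION = 0.41


# ---------------------------------------------------------------------------
# analytic geometry

def sphere_volume(r: float) -> float:
    return 4.0 / 3.0 * math.pi * r**3


def sphere_surface(r: float) -> float:
    return 4.0 * math.pi * r**2


def isocontour_radius(sigma: float, fraction: float = DEFAULT_FRACTION) -> float:
    """Radius where a Gaussian profile peak*exp(-r^2 / 2 sigma^2) falls to
    ``fraction`` of its peak: r* = sigma * sqrt(2 ln(1/fraction))."""
    return sigma * math.sqrt(2.0 * math.log(1.0 / fraction))


def ellipsoid_surface(semi_axes) -> float:
    """Exact ellipsoid surface area via Legendre incomplete elliptic integrals."""
    a, b, c = sorted((float(x) for x in semi_axes), reverse=True)
    if a <= 0:
        raise ValueError("semi-axes must be positive")
    if (a - c) / a < 1e-9:
        return sphere_surface((a * b * c) ** (1.0 / 3.0))
    phi = math.acos(c / a)
    m = (a**2 * (b**2 - c**2)) / (b**2 * (a**2 - c**2))
    F = special.ellipkinc(phi, m)
    E = special.ellipeinc(phi, m)
    s = math.sin(phi)
    return float(2 * math.pi * c**2 + (2 * math.pi * a * b / s) * (E * s**2 + F * math.cos(phi) ** 2))


# ---------------------------------------------------------------------------
# phantom specification

@dataclass
class LesionSpec:
    """One synthetic lesion.

    ``shape`` is 'sphere' (radius), 'ellipsoid' (semi_axes) or
    'gaussian_blob' (sigma); the SUV profile is uniform at ``peak_suv``
    for the solid shapes and Gaussian for the blob. ``site`` may be omitted,
    in which case the diaphragm side is derived from the center and the
    lesion is treated as nodal.
    """

    center: tuple[float, float, float]
    shape: str
    peak_suv: float
    radius: float | None = None
    semi_axes: tuple[float, float, float] | None = None
    sigma: float | None = None
    site: SiteAnnotation | None = None

    def __post_init__(self):
        if self.shape not in ("sphere", "ellipsoid", "gaussian_blob"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.peak_suv <= 0:
            raise ValueError("peak_suv must be > 0")
        if self.shape == "sphere":
            if not self.radius or self.radius <= 0:
                raise ValueError("sphere needs radius > 0")
        elif self.shape == "ellipsoid":
            if self.semi_axes is None or any(s <= 0 for s in self.semi_axes):
                raise ValueError("ellipsoid needs three positive semi-axes")
        else:
            if not self.sigma or self.sigma <= 0:
                raise ValueError("gaussian_blob needs sigma > 0")

    def support_extent(self, fraction: float = DEFAULT_FRACTION) -> np.ndarray:
        """Half-extent (mm per axis) of the 41%-iso-contour solid."""
        if self.shape == "sphere":
            return np.full(3, self.radius)
        if self.shape == "ellipsoid":
            return np.asarray(self.semi_axes, dtype=float)
        return np.full(3, isocontour_radius(self.sigma, fraction))

    def truth_row(self, fraction: float = DEFAULT_FRACTION) -> dict:
        """Analytic volume/surface/diameter of the iso-contour solid."""
        if self.shape == "sphere":
            v, s, d = sphere_volume(self.radius), sphere_surface(self.radius), 2 * self.radius
        elif self.shape == "ellipsoid":
            a, b, c = self.semi_axes
            v = 4.0 / 3.0 * math.pi * a * b * c
            s = ellipsoid_surface(self.semi_axes)
            d = 2 * max(self.semi_axes)
        else:
            r = isocontour_radius(self.sigma, fraction)
            v, s, d = sphere_volume(r), sphere_surface(r), 2 * r
        return {"volume_mm3": v, "surface_mm2": s, "diameter_mm": d}


@dataclass
class PhantomSpec:
    """A synthetic SUV volume: grid geometry, uniform background, additive
    Gaussian noise (truncated at zero) and a list of lesions."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_suv: float = 0.5
    noise_sd: float = 0.0
    lesions: list[LesionSpec] = field(default_factory=list)
    seed: int = 0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    diaphragm_z: float | None = None

    def __post_init__(self):
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 8 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.background_suv < 0 or self.noise_sd < 0:
            raise ValueError("background_suv and noise_sd must be >= 0")
        for i, les in enumerate(self.lesions):
            if les.peak_suv <= self.background_suv:
                raise ValueError(f"lesion {i}: peak_suv must exceed background_suv")


@dataclass
class CohortTruth:
    """Generator-side ground truth for recovery tests."""

    lesions: pd.DataFrame | None = None
    patients: pd.DataFrame | None = None
    log_hr: dict | None = None
    phantom_specs: list | None = None


# ---------------------------------------------------------------------------
# phantom rasterization

def _derived_side(center_z: float, diaphragm_z: float) -> Side:
    return Side.ABOVE if center_z > diaphragm_z else Side.BELOW


def make_phantom(spec: PhantomSpec, fraction: float = DEFAULT_FRACTION):
    """Rasterize a phantom; returns (SUVVolume, CohortTruth).

    Lesion profiles are composed with the background by voxelwise maximum, so
    a uniform lesion reads exactly ``peak_suv`` and a Gaussian blob keeps its
    closed-form iso-contour. Lesions that extend outside the grid are
    rejected, as are overlapping lesions carrying different site annotations
    (their truth would be ambiguous).
    """
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    origin = np.asarray(spec.origin, dtype=float)
    lo = origin
    hi = origin + (np.asarray(shape) - 1) * spacing
    diaphragm = spec.diaphragm_z if spec.diaphragm_z is not None else lo[2] + (hi[2] - lo[2]) / 2

    axes = [origin[d] + spacing[d] * np.arange(shape[d]) for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    values = np.full(shape, float(spec.background_suv))
    owner = np.zeros(shape, dtype=np.int32)  # 41%-support ownership, 1-based

    rows = []
    for i, les in enumerate(spec.lesions):
        c = np.asarray(les.center, dtype=float)
        ext = les.support_extent(fraction)
        if np.any(c - ext < lo) or np.any(c + ext > hi):
            raise ValueError(
                f"lesion {i} ({les.shape}, center {c.tolist()}) extends outside the grid "
                f"[{lo.tolist()} .. {hi.tolist()}]"
            )
        dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
        if les.shape == "sphere":
            support = dx**2 + dy**2 + dz**2 <= les.radius**2
            profile = np.where(support, les.peak_suv, 0.0)
        elif les.shape == "ellipsoid":
            a, b, cc = les.semi_axes
            support = (dx / a) ** 2 + (dy / b) ** 2 + (dz / cc) ** 2 <= 1.0
            profile = np.where(support, les.peak_suv, 0.0)
        else:
            r2 = dx**2 + dy**2 + dz**2
            profile = les.peak_suv * np.exp(-r2 / (2.0 * les.sigma**2))
            support = r2 <= isocontour_radius(les.sigma, fraction) ** 2

        site = les.site or SiteAnnotation(
            side=_derived_side(c[2], diaphragm), compartment=Compartment.NODAL, organ_id=f"node_{i}"
        )
        if les.site is not None and les.site.side is not _derived_side(c[2], diaphragm):
            raise ValueError(
                f"lesion {i}: annotated side {les.site.side.value} conflicts with center "
                f"z={c[2]} vs diaphragm plane z={diaphragm}"
            )
        clash = owner[support]
        clash = np.unique(clash[clash > 0])
        for j in clash:
            other = rows[j - 1]
            if (other["side"], other["compartment"], other["organ_id"]) != (
                site.side.value, site.compartment.value, site.organ_id
            ):
                raise ValueError(
                    f"lesions {j - 1} and {i} overlap but carry different site labels; "
                    "ground truth would be ambiguous"
                )
        owner[support] = i + 1
        values = np.maximum(values, profile)
        row = {"lesion": i, "shape": les.shape, "peak_suv": les.peak_suv,
               "center_x": c[0], "center_y": c[1], "center_z": c[2],
               "side": site.side.value, "compartment": site.compartment.value,
               "organ_id": site.organ_id}
        row.update(les.truth_row(fraction))
        rows.append(row)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
        values = np.clip(values + rng.normal(0.0, spec.noise_sd, size=shape), 0.0, None)

    vol = SUVVolume(values=values, spacing=spacing, origin=origin)
    truth = CohortTruth(lesions=pd.DataFrame(rows))
    return vol, truth


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults mirror a CAR-T lymphoma cohort: roughly a quarter of patients
    bulky, a third extra-stage, a median uncensored event time near one year
    (baseline hazard 1/500 per day) and administrative censoring within a
    two-year follow-up window.
    """

    n_patients: int = 42
    p_bulky: float = 0.26
    p_extra: float = 0.33
    baseline_hazard: float = 1.0 / 500.0
    log_hr_bulky: float = math.log(2.5)
    log_hr_extra: float = math.log(2.5)
    censor_window: float = 730.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (0 <= self.p_bulky <= 1 and 0 <= self.p_extra <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.baseline_hazard <= 0 or self.censor_window <= 0:
            raise ValueError("baseline_hazard and censor_window must be > 0")


def _patient_lesions(rng: np.random.Generator, bulky: bool, extra: bool) -> list[dict]:
    """Analytic sphere lesions consistent with the patient's flags.

    Non-bulky radii stay below 24 mm (diameter < 48 mm); a bulky patient gets
    one mass of 28-40 mm radius. Extra-stage patients have lesions on both
    diaphragm sides and two distinct extranodal organs; others stay above the
    diaphragm with at most one extranodal site.
    """
    lesions = []
    n_base = int(rng.integers(1, 4))
    for i in range(n_base):
        r = float(rng.uniform(6.0, 18.0))
        lesions.append({"radius": r, "side": Side.ABOVE, "compartment": Compartment.NODAL,
                        "organ_id": f"node_{i}"})
    if bulky:
        lesions.append({"radius": float(rng.uniform(28.0, 40.0)), "side": Side.ABOVE,
                        "compartment": Compartment.NODAL, "organ_id": "node_bulk"})
    if extra:
        lesions.append({"radius": float(rng.uniform(6.0, 15.0)), "side": Side.BELOW,
                        "compartment": Compartment.EXTRANODAL, "organ_id": "liver"})
        lesions.append({"radius": float(rng.uniform(6.0, 15.0)), "side": Side.ABOVE,
                        "compartment": Compartment.EXTRANODAL, "organ_id": "lung"})
    elif rng.random() < 0.3:  # occasional single extranodal site, still not extra-stage
        lesions[0]["compartment"] = Compartment.EXTRANODAL
        lesions[0]["organ_id"] = "lung"
    return lesions


def make_cohort(spec: CohortSpec, attach_phantoms: bool = False,
                phantom_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)):
    """Simulate a cohort; returns (patients DataFrame, CohortTruth).

    Indicators (TMTV/TTS/TVSR, flags, synergy group) are computed from the
    analytic sphere lesions; PFS event times follow the proportional-hazards
    inverse transform with uniform censoring on (0, censor_window); OS adds an
    independent exponential post-progression time under the same linear
    predictor at half the baseline hazard; complete response is drawn from a
    logistic model on TVSR and the two flags.
    """
    ss = np.random.SeedSequence(spec.seed)
    flags_rng, geom_rng, surv_rng = (np.random.default_rng(c) for c in ss.spawn(3))

    x_bulky = flags_rng.random(spec.n_patients) < spec.p_bulky
    x_extra = flags_rng.random(spec.n_patients) < spec.p_extra

    rows, truth_rows, lesion_rows, specs = [], [], [], []
    for i in range(spec.n_patients):
        les = _patient_lesions(geom_rng, bool(x_bulky[i]), bool(x_extra[i]))
        radii = np.array([l["radius"] for l in les])
        tmtv = float(sum(sphere_volume(r) for r in radii))
        tts = float(sum(sphere_surface(r) for r in radii))
        tvsr = tmtv / tts
        diam = float(2 * radii.max())
        bulky = diam > BULKY_DIAMETER_MM
        sides = {l["side"] for l in les}
        organs = {l["organ_id"] for l in les if l["compartment"] is Compartment.EXTRANODAL}
        extra = (Side.ABOVE in sides and Side.BELOW in sides) and len(organs) > 1
        # Ann Arbor-consistent stage for the synthetic record only
        if Side.ABOVE in sides and Side.BELOW in sides:
            stage = "IV" if organs else "III"
        else:
            stage = "II" if len(les) > 1 else "I"

        lp = spec.log_hr_bulky * bulky + spec.log_hr_extra * extra
        u = surv_rng.random()
        t_pfs = -math.log(u) / (spec.baseline_hazard * math.exp(lp))
        t_os = t_pfs + surv_rng.exponential(1.0 / (0.5 * spec.baseline_hazard * math.exp(lp)))
        censor = surv_rng.uniform(0.0, spec.censor_window)
        logit_cr = 2.0 - 0.35 * tvsr - 0.7 * bulky - 0.7 * extra
        cr = surv_rng.random() < 1.0 / (1.0 + math.exp(-logit_cr))

        rows.append({
            "patient_id": f"P{i:04d}",
            "n_lesions": len(les),
            "tmtv_mm3": tmtv,
            "tts_mm2": tts,
            "tvsr_mm": tvsr,
            "max_diameter_mm": diam,
            "bulky": bulky,
            "extra_stage": extra,
            "stage": stage,
            "stage_3_4": stage in ("III", "IV"),
            "extranodal_gt1": len(organs) > 1,
            "synergy_group": synergy_group(bulky, extra),
            "pfs_days": min(t_pfs, censor),
            "pfs_event": t_pfs <= censor,
            "os_days": min(t_os, censor),
            "os_event": t_os <= censor,
            "cr": cr,
        })
        truth_rows.append({
            "patient_id": f"P{i:04d}",
            "true_bulky": bool(x_bulky[i]),
            "true_extra": bool(x_extra[i]),
            "t_pfs_uncensored": t_pfs,
            "t_os_uncensored": t_os,
            "censor_time": censor,
        })
        for j, l in enumerate(les):
            lesion_rows.append({
                "patient_id": f"P{i:04d}", "lesion": j, "radius_mm": l["radius"],
                "volume_mm3": sphere_volume(l["radius"]),
                "surface_mm2": sphere_surface(l["radius"]),
                "side": l["side"].value, "compartment": l["compartment"].value,
                "organ_id": l["organ_id"],
            })
        if attach_phantoms:
            specs.append(phantom_spec_for_patient(les, spacing=phantom_spacing, seed=spec.seed + i))

    patients = pd.DataFrame(rows)
    truth = CohortTruth(
        lesions=pd.DataFrame(lesion_rows),
        patients=pd.DataFrame(truth_rows),
        log_hr={"bulky": spec.log_hr_bulky, "extra_stage": spec.log_hr_extra},
        phantom_specs=specs if attach_phantoms else None,
    )
    return patients, truth


def phantom_spec_for_patient(lesions: list[dict], spacing=(2.0, 2.0, 2.0),
                             background_suv: float = 0.5, peak_suv: float = 8.0,
                             seed: int = 0) -> PhantomSpec:
    """Lay a patient's sphere lesions out on a grid, above-diaphragm lesions
    in the upper z half and below-diaphragm in the lower, with enough margin
    that supports never overlap."""
    spacing = np.asarray(spacing, dtype=float)
    radii = [l["radius"] for l in lesions]
    pad = 3.0 * float(spacing.max())
    slot = 2 * max(radii) + 2 * pad
    n_above = sum(1 for l in lesions if l["side"] is Side.ABOVE)
    n_below = len(lesions) - n_above
    n_cols = max(n_above, n_below, 1)
    width = n_cols * slot
    height = 2 * slot
    shape = tuple(int(math.ceil(w / s)) + 2 for w, s in zip((width, slot, height), spacing))
    shape = tuple(max(n, 8) for n in shape)
    lo = np.zeros(3)
    hi = lo + (np.asarray(shape) - 1) * spacing
    diaphragm = (lo[2] + hi[2]) / 2

    specs = []
    i_above = i_below = 0
    y = (lo[1] + hi[1]) / 2
    for l in lesions:
        if l["side"] is Side.ABOVE:
            x = lo[0] + slot * (i_above + 0.5)
            z = diaphragm + slot / 2
            i_above += 1
        else:
            x = lo[0] + slot * (i_below + 0.5)
            z = diaphragm - slot / 2
            i_below += 1
        specs.append(LesionSpec(
            center=(float(x), float(y), float(z)), shape="sphere", radius=l["radius"],
            peak_suv=peak_suv,
            site=SiteAnnotation(side=l["side"], compartment=l["compartment"], organ_id=l["organ_id"]),
        ))
    return PhantomSpec(grid_shape=shape, spacing=tuple(spacing), background_suv=background_suv,
                       noise_sd=0.0, lesions=specs, seed=seed, diaphragm_z=diaphragm)
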