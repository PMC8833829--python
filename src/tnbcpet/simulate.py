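"""Synthetic inputs: lesion PET volumes, the NEMA IQ phantom, cohorts, flow fixture.

Everything the pipeline consumes can be generated here, seeded and
deterministic:

* hypermetabolic breast-lesion volumes — an ellipsoidal lesion with a chosen
  intensity model (uniform, voxel-wise Gaussian noise, a hot two-compartment
  core, or a center-to-rim gradient) painted on a low-uptake background and
  optionally blurred by an isotropic Gaussian point-spread function standing
  in for PET resolution;
* the NEMA NU2 image-quality phantom: six coaxial spheres (10–37 mm inner
  diameter) at a 5:1 sphere-to-background activity ratio, for recovery-
  coefficient QC;
* survival cohorts whose relapse hazard follows a proportional-hazards model
  on (log MTV, log TLG, entropy, N+PET) with independent censoring, and death
  occurring only after relapse (so DFS <= OS by construction);
* the screening-flow fixture: one record per screened patient with
  eligibility attributes arranged so each exclusion reason claims exactly its
  tabulated count, and the enrolled remainder carrying the tabulated clinical
  mix and outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imaging import PetVolume, SuvVolume, ValidationError, VolumeMeta
from .segmentation import RoiBox

__all__ = [
    "LesionSpec",
    "CohortSpec",
    "make_lesion_volume",
    "make_nema_phantom",
    "sphere_recovery",
    "make_patient_features",
    "make_cohort",
    "make_flow_fixture",
    "make_patient_volume",
    "NEMA_DIAMETERS_MM",
    "RELAPSE_TYPES",
]

NEMA_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)

RELAPSE_TYPES = ("metastatic", "locoregional", "contralateral", "second cancer")

#: Default acquisition metadata: 70 kg patient given 2.5 MBq/kg.
_DEFAULT_META = dict(injected_activity_bq=1.75e8, body_weight_g=7.0e4)


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


# ---------------------------------------------------------------------------
# Lesion volumes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LesionSpec:
    """One synthetic lesion: geometry, intensity and heterogeneity model.

    ``model`` is one of ``"uniform"``, ``"gaussian-noise"`` (voxel-wise noise
    of SD ``noise_sd``), ``"two-compartment"`` (a concentric core of volume
    fraction ``core_fraction`` at ``core_suv``) or ``"gradient"`` (linear
    decrease from ``base_suv`` at the center to half at the rim).
    """

    center_vox: tuple[int, int, int]
    radius_mm: float | tuple[float, float, float]
    base_suv: float
    model: str = "uniform"
    noise_sd: float = 1.0
    core_suv: float | None = None
    core_fraction: float = 0.3
    seed: int = 0

    @property
    def semi_axes_mm(self) -> tuple[float, float, float]:
        r = self.radius_mm
        return (r, r, r) if np.isscalar(r) else tuple(r)


def make_lesion_volume(
    spec: LesionSpec,
    shape: tuple[int, int, int] = (48, 48, 48),
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    background_suv: float = 0.5,
    psf_fwhm_mm: float = 0.0,
    scanner: str = "unknown",
) -> tuple[PetVolume, dict]:
    """Paint a lesion on a low-uptake background, optionally PSF-blurred.

    Returns the activity volume plus ground truth computed from the painted
    (pre-blur) mask: the true voxelized MTV and SUV statistics.
    """
    axes = np.asarray(spec.semi_axes_mm, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    if np.any(axes < sp.min()):
        raise ValidationError("lesion radius must exceed one voxel")
    center_mm = np.asarray(spec.center_vox, dtype=float) * sp
    lo = center_mm - axes
    hi = center_mm + axes
    extent_mm = np.asarray(shape) * sp
    if np.any(lo < 0) or np.any(hi > extent_mm):
        raise ValidationError("lesion exceeds the grid")

    idx = np.indices(shape, dtype=float)
    norm2 = np.zeros(shape)
    for ax in range(3):
        norm2 += ((idx[ax] * sp[ax] - center_mm[ax]) / axes[ax]) ** 2
    mask = norm2 <= 1.0

    rng = np.random.default_rng(spec.seed)
    suv = np.full(shape, float(background_suv))
    if spec.model == "uniform":
        suv[mask] = spec.base_suv
    elif spec.model == "gaussian-noise":
        suv[mask] = np.clip(
            spec.base_suv + rng.normal(0.0, spec.noise_sd, size=int(mask.sum())), 0.0, None
        )
    elif spec.model == "two-compartment":
        if spec.core_suv is None:
            raise ValidationError("two-compartment model needs core_suv")
        core = norm2 <= spec.core_fraction ** (2.0 / 3.0)
        suv[mask] = spec.base_suv
        suv[core & mask] = spec.core_suv
    elif spec.model == "gradient":
        r = np.sqrt(norm2[mask])
        suv[mask] = spec.base_suv * (1.0 - 0.5 * r)
    else:
        raise ValidationError(f"unknown heterogeneity model {spec.model!r}")

    truth_vals = suv[mask]
    truth = {
        "mask": mask,
        "mtv_cm3": float(mask.sum() * sp.prod() / 1000.0),
        "suv_max": float(truth_vals.max()),
        "suv_mean": float(truth_vals.mean()),
    }

    if psf_fwhm_mm > 0:
        sigma_vox = _fwhm_to_sigma(psf_fwhm_mm) / sp
        suv = ndi.gaussian_filter(suv, sigma=sigma_vox)

    meta = VolumeMeta(scanner=scanner, **_DEFAULT_META)
    conc = suv * (meta.injected_activity_bq / meta.body_weight_g)
    return PetVolume(grid=conc, spacing=tuple(spacing), meta=meta), truth


# ---------------------------------------------------------------------------
# NEMA image-quality phantom
# ---------------------------------------------------------------------------


def make_nema_phantom(
    sbr: float = 5.0,
    sphere_diameters_mm: tuple[float, ...] = NEMA_DIAMETERS_MM,
    background_suv: float = 1.0,
    psf_fwhm_mm: float = 0.0,
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    shape: tuple[int, int, int] = (96, 96, 48),
    ring_radius_mm: float = 57.2,
    scanner: str = "phantom",
) -> tuple[PetVolume, dict]:
    """Six coaxial spheres at ``sbr`` x background, optionally PSF-blurred.

    Sphere centers sit on a ring of radius 57.2 mm in the central transaxial
    plane, 60 degrees apart, as in the NU2 image-quality phantom.
    """
    sp = np.asarray(spacing, dtype=float)
    center_mm = np.asarray(shape, dtype=float) * sp / 2.0
    suv = np.full(shape, float(background_suv))
    idx = np.indices(shape, dtype=float)
    coords_mm = [idx[ax] * sp[ax] for ax in range(3)]

    centers = []
    for k, diam in enumerate(sphere_diameters_mm):
        angle = 2.0 * math.pi * k / len(sphere_diameters_mm)
        c = np.array(
            [
                center_mm[0] + ring_radius_mm * math.cos(angle),
                center_mm[1] + ring_radius_mm * math.sin(angle),
                center_mm[2],
            ]
        )
        r = diam / 2.0
        if np.any(c - r < 0) or np.any(c + r > np.asarray(shape) * sp):
            raise ValidationError("phantom sphere exceeds the grid")
        d2 = sum((coords_mm[ax] - c[ax]) ** 2 for ax in range(3))
        suv[d2 <= r**2] = sbr * background_suv
        centers.append(tuple(c))

    if psf_fwhm_mm > 0:
        suv = ndi.gaussian_filter(suv, sigma=_fwhm_to_sigma(psf_fwhm_mm) / sp)

    meta = VolumeMeta(scanner=scanner, **_DEFAULT_META)
    conc = suv * (meta.injected_activity_bq / meta.body_weight_g)
    info = {
        "centers_mm": centers,
        "diameters_mm": tuple(sphere_diameters_mm),
        "background_suv": background_suv,
        "sbr": sbr,
    }
    return PetVolume(grid=conc, spacing=tuple(spacing), meta=meta), info


def sphere_recovery(suv: SuvVolume, info: dict) -> list[float]:
    """SUVmax recovery coefficient per sphere: measured max / true sphere SUV."""
    sp = np.asarray(suv.spacing, dtype=float)
    idx = np.indices(suv.grid.shape, dtype=float)
    coords_mm = [idx[ax] * sp[ax] for ax in range(3)]
    true_suv = info["sbr"] * info["background_suv"]
    out = []
    for c, diam in zip(info["centers_mm"], info["diameters_mm"]):
        d2 = sum((coords_mm[ax] - c[ax]) ** 2 for ax in range(3))
        region = d2 <= (diam / 2.0) ** 2
        out.append(float(suv.grid[region].max() / true_suv))
    return out


# ---------------------------------------------------------------------------
# Cohorts with feature-linked hazards
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Proportional-hazards cohort: log-HR coefficients, baseline, censoring.

    The relapse hazard is ``baseline_rate * exp(beta . (x - mean(x)))`` with
    x = (log MTV, log TLG, entropy, N+PET); death happens only after relapse,
    delayed by an exponential residual. Censoring is uniform on
    ``censor_range_months`` (staggered accrual), truncated at ``horizon``.
    """

    n: int = 111
    beta_log_mtv: float = math.log(1.4)
    beta_log_tlg: float = 0.0
    beta_entropy: float = math.log(2.0)
    beta_n_pet: float = math.log(2.9)
    baseline_rate: float = 0.0065
    death_delay_mean_months: float = 12.0
    censor_range_months: tuple[float, float] = (12.0, 84.0)
    horizon: float = 84.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValidationError("cohort needs n >= 10")
        if self.baseline_rate <= 0 or self.death_delay_mean_months <= 0:
            raise ValidationError("rates must be positive")


def make_patient_features(
    n: int,
    seed: int | np.random.Generator = 0,
    scanner_probs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Feature-level cohort generator emulating the study's marginals.

    A latent severity score drives correlated MTV, SUV, entropy, nodal status
    and T stage, with lognormal MTV/SUV scales matching the reported medians
    (MTV median ~6.8 cm^3 with a heavy tail, SUVmean median ~5.3, SUVmax
    median ~12.8) and N+PET prevalence ~45%.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if scanner_probs is None:
        scanner_probs = {"DST": 45 / 111, "D690": 49 / 111, "DIQ5": 17 / 111}
    s = rng.normal(size=n)  # latent severity

    log_mtv = math.log(6.8) + 1.55 * (0.8 * s + 0.6 * rng.normal(size=n))
    mtv = np.exp(log_mtv)
    suv_mean = np.exp(math.log(5.3) + 0.35 * (0.6 * s + 0.8 * rng.normal(size=n)))
    ratio = np.exp(rng.normal(math.log(2.4), 0.15, size=n))
    suv_max = suv_mean * ratio
    suv_peak = suv_max * np.clip(rng.normal(0.85, 0.05, size=n), 0.6, 1.0)
    entropy = np.clip(2.6 + 0.35 * (0.7 * s + 0.7 * rng.normal(size=n)), 0.3, 6.0)
    homogeneity = np.clip(0.45 - 0.05 * s + 0.05 * rng.normal(size=n), 0.05, 1.0)
    sre = np.clip(0.93 + 0.02 * rng.normal(size=n), 0.6, 1.0)
    lre = np.clip(1.6 + 0.3 * rng.normal(size=n), 1.0, None)
    lgze = np.clip(0.05 + 0.02 * rng.normal(size=n), 1e-4, 1.0)
    hgze = np.clip(120 + 40 * s + 30 * rng.normal(size=n), 1.0, None)

    def _bern(p):
        return (rng.random(n) < p).astype(int)

    logit_npet = math.log(0.45 / 0.55) + 0.8 * s
    n_pet = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit_npet))).astype(int)
    logit_t34 = math.log(0.282 / 0.718) + 0.7 * s
    t34 = rng.random(n) < 1.0 / (1.0 + np.exp(-logit_t34))

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "scanner": rng.choice(list(scanner_probs), size=n, p=list(scanner_probs.values())),
            "suv_max": suv_max,
            "suv_mean": suv_mean,
            "suv_peak": suv_peak,
            "mtv_cm3": mtv,
            "tlg": suv_mean * mtv,
            "homogeneity": homogeneity,
            "entropy": entropy,
            "sre": sre,
            "lre": lre,
            "lgze": lgze,
            "hgze": hgze,
            "n_pet": n_pet,
            "t_stage": np.where(t34, "T3-T4", "T1-T2"),
            "inflammatory": _bern(0.109).astype(bool),
            "grade": np.where(_bern(0.928), 3, 2),
            "multifocal": _bern(0.225).astype(bool),
            "age": np.clip(rng.normal(52.6, 14.7, size=n), 25, 90),
        }
    )


def make_cohort(spec: CohortSpec, features: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach DFS/OS outcomes drawn from the proportional-hazards model.

    ``features`` needs columns mtv_cm3, tlg, entropy, n_pet; by default a
    feature table of size ``spec.n`` is generated from the same seed.
    """
    rng = np.random.default_rng(spec.seed)
    if features is None:
        features = make_patient_features(spec.n, seed=rng)
    df = features.copy().reset_index(drop=True)
    n = len(df)

    X = np.column_stack(
        [
            np.log(df["mtv_cm3"].to_numpy(dtype=float)),
            np.log(df["tlg"].to_numpy(dtype=float)),
            df["entropy"].to_numpy(dtype=float),
            df["n_pet"].to_numpy(dtype=float),
        ]
    )
    beta = np.array([spec.beta_log_mtv, spec.beta_log_tlg, spec.beta_entropy, spec.beta_n_pet])
    lp = (X - X.mean(axis=0)) @ beta
    hazard = spec.baseline_rate * np.exp(lp)

    relapse = rng.exponential(1.0 / hazard)
    lo, hi = spec.censor_range_months
    censor = np.minimum(rng.uniform(lo, hi, size=n), spec.horizon)
    death = relapse + rng.exponential(spec.death_delay_mean_months, size=n)

    dfs_months = np.minimum(relapse, censor)
    dfs_event = (relapse <= censor).astype(int)
    os_months = np.minimum(death, censor)
    os_event = (death <= censor).astype(int)

    relapse_type = np.array(["none"] * n, dtype=object)
    relapsed = dfs_event == 1
    relapse_type[relapsed] = rng.choice(
        RELAPSE_TYPES, size=int(relapsed.sum()), p=(23 / 34, 9 / 34, 1 / 34, 1 / 34)
    )

    df["dfs_months"] = np.maximum(dfs_months, 1e-3)
    df["dfs_event"] = dfs_event
    df["os_months"] = np.maximum(os_months, 1e-3)
    df["os_event"] = os_event
    df["relapse_type"] = relapse_type
    return df


# ---------------------------------------------------------------------------
# Image-route patient generator
# ---------------------------------------------------------------------------


def make_patient_volume(
    severity: float,
    seed: int,
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    psf_fwhm_mm: float = 6.0,
    scanner: str = "unknown",
    multifocal_prob: float = 0.225,
) -> tuple[PetVolume, RoiBox]:
    """One patient's lesion volume, geometry and heterogeneity tied to severity.

    Larger severity yields a bigger, hotter, more heterogeneous lesion; with
    probability ``multifocal_prob`` a second smaller focus is added.
    """
    rng = np.random.default_rng(seed)
    target_mtv = math.exp(math.log(6.8) + 1.1 * (0.8 * severity + 0.6 * rng.normal()))
    target_mtv = float(np.clip(target_mtv, 1.0, 120.0))
    radius = (3.0 * target_mtv * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    base_suv = float(
        np.clip(np.exp(math.log(8.0) + 0.35 * (0.6 * severity + 0.8 * rng.normal())), 3.0, 30.0)
    )
    noise_sd = float(np.clip(0.18 * base_suv * (1.0 + 0.4 * severity), 0.2, 6.0))

    sp = np.asarray(spacing)
    margin_vox = int(math.ceil((radius + 4 * psf_fwhm_mm / 2.355 + 6.0) / sp.min()))
    half = margin_vox + 2
    shape = tuple(int(2 * half) for _ in range(3))
    center = tuple(half for _ in range(3))
    spec = LesionSpec(
        center_vox=center,
        radius_mm=radius,
        base_suv=base_suv,
        model="gaussian-noise",
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    vol, _ = make_lesion_volume(
        spec, shape=shape, spacing=spacing, background_suv=0.5, psf_fwhm_mm=0.0, scanner=scanner
    )
    suv_grid = vol.grid / (vol.meta.injected_activity_bq / vol.meta.body_weight_g)

    if rng.random() < multifocal_prob:
        r2 = max(radius * 0.45, sp.min() * 1.5)
        offset = int(math.ceil((radius + r2 + 6.0) / sp.min()))
        c2 = (min(center[0] + offset, shape[0] - int(r2 / sp[0]) - 2), center[1], center[2])
        spec2 = LesionSpec(
            center_vox=c2,
            radius_mm=r2,
            base_suv=base_suv * 0.7,
            model="gaussian-noise",
            noise_sd=noise_sd * 0.7,
            seed=int(rng.integers(2**31 - 1)),
        )
        vol2, _ = make_lesion_volume(
            spec2, shape=shape, spacing=spacing, background_suv=0.0, psf_fwhm_mm=0.0, scanner=scanner
        )
        suv2 = vol2.grid / (vol2.meta.injected_activity_bq / vol2.meta.body_weight_g)
        suv_grid = np.maximum(suv_grid, suv2)

    if psf_fwhm_mm > 0:
        suv_grid = ndi.gaussian_filter(suv_grid, sigma=_fwhm_to_sigma(psf_fwhm_mm) / sp)

    meta = VolumeMeta(scanner=scanner, **_DEFAULT_META)
    conc = suv_grid * (meta.injected_activity_bq / meta.body_weight_g)
    return PetVolume(grid=conc, spacing=tuple(spacing), meta=meta), RoiBox((0, 0, 0), shape)


# ---------------------------------------------------------------------------
# Screening-flow fixture
# ---------------------------------------------------------------------------

#: (reason label, count) in the order exclusions are attributed.
FLOW_EXCLUSIONS = (
    ("receptor_positive", 245),
    ("prior_cancer", 277),
    ("metastatic", 30),
    ("surgery_before_pet", 13),
    ("low_uptake", 3),
)

FLOW_ENROLLED = 111


def make_flow_fixture() -> pd.DataFrame:
    """Deterministic screening table: 679 records, 568 excluded, 111 enrolled.

    Exclusion attributes are set so each reason claims exactly its tabulated
    count under first-reason attribution (a handful of receptor-positive
    records also carry a prior-cancer flag, exercising the ordering rule).
    The enrolled 111 carry the tabulated clinical mix — scanners 45/49/17,
    50 N+PET, 80 T1–T2, 103 grade 3, 12 inflammatory, 25 multifocal — and
    outcomes with 34 relapses (23 metastatic / 9 locoregional /
    1 contralateral / 1 second cancer) and 20 deaths.
    """
    rows: list[dict] = []

    def base_row(pid: int) -> dict:
        return {
            "patient_id": f"S{pid:04d}",
            "er_positive": False,
            "pr_positive": False,
            "her2_positive": False,
            "prior_cancer": False,
            "metastatic": False,
            "surgery_before_pet": False,
            "suv_max": 8.0,
            "scanner": None,
            "n_pet": None,
            "t_stage": None,
            "inflammatory": None,
            "grade": None,
            "multifocal": None,
            "age": None,
            "dfs_months": None,
            "dfs_event": None,
            "os_months": None,
            "os_event": None,
            "relapse_type": None,
        }

    pid = 0
    for i in range(245):
        r = base_row(pid)
        r["er_positive"] = True
        if i < 40:  # overlap: also prior cancer; still attributed to receptors
            r["prior_cancer"] = True
        rows.append(r)
        pid += 1
    for _ in range(277):
        r = base_row(pid)
        r["prior_cancer"] = True
        rows.append(r)
        pid += 1
    for _ in range(30):
        r = base_row(pid)
        r["metastatic"] = True
        rows.append(r)
        pid += 1
    for _ in range(13):
        r = base_row(pid)
        r["surgery_before_pet"] = True
        rows.append(r)
        pid += 1
    for _ in range(3):
        r = base_row(pid)
        r["suv_max"] = 1.8
        rows.append(r)
        pid += 1

    scanners = ["DST"] * 45 + ["D690"] * 49 + ["DIQ5"] * 17
    relapse_labels = (
        ["metastatic"] * 23 + ["locoregional"] * 9 + ["contralateral"] + ["second cancer"]
    )
    for i in range(FLOW_ENROLLED):
        r = base_row(pid)
        r["suv_max"] = 3.0 + (i % 28) * 1.1
        r["scanner"] = scanners[i]
        r["n_pet"] = i < 50
        r["t_stage"] = "T1-T2" if i < 80 else "T3-T4"
        r["inflammatory"] = i % 9 == 0 and i < 108  # 12 of 111
        r["grade"] = 2 if i >= 103 else 3
        r["multifocal"] = i % 4 == 0 and i < 100  # 25 of 111
        r["age"] = 25 + (i * 65.0 / 110.0)
        if i < 34:  # relapses, mostly within two years
            relapse_t = 4.0 + 0.6 * i if i < 30 else 30.0 + 6.0 * (i - 30)
            r["dfs_months"] = relapse_t
            r["dfs_event"] = 1
            r["relapse_type"] = relapse_labels[i]
            if i < 20:  # deaths among relapsers
                r["os_months"] = relapse_t + 8.0
                r["os_event"] = 1
            else:
                r["os_months"] = relapse_t + 20.0
                r["os_event"] = 0
        else:
            censor_t = 30.0 + (i % 50)
            r["dfs_months"] = censor_t
            r["dfs_event"] = 0
            r["os_months"] = censor_t
            r["os_event"] = 0
            r["relapse_type"] = "none"
        rows.append(r)
        pid += 1

    return pd.DataFrame(rows)
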