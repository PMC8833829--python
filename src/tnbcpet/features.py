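"""Per-tumor PET features: SUV statistics, MTV, TLG and six texture features.

Texture analysis follows the fixed-bin convention used for FDG-PET tumors:
the VOI is discretized with absolute bounds 0–20 SUV into 64 gray levels
(bin width 0.3125 SUV), then a single pooled gray-level co-occurrence matrix
(GLCM), run-length matrix (GLRLM) and size-zone matrix (GLSZM) are built over
the 13 unique 3-D directions at distance one voxel (26-connectivity for
zones). Six scalars summarize them: homogeneity and entropy (GLCM, entropy in
bits), short- and long-run emphasis (GLRLM), and low-/high-gray-level zone
emphasis (GLSZM).

Multifocal tumors aggregate as: MTV sums, SUVmean is the MTV-weighted mean,
TLG sums (which keeps TLG = SUVmean x MTV exact), while SUVmax, SUVpeak and
the texture features come from the index (most avid) lesion alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .imaging import SuvVolume, ValidationError
from .segmentation import STRUCT_26, LesionMask, select_index_lesion, threshold_voi

__all__ = [
    "DiscretizedVoi",
    "FeatureVector",
    "FEATURE_COLUMNS",
    "TEXTURE_NAMES",
    "MIN_TEXTURE_VOXELS",
    "suv_statistics",
    "suv_peak",
    "metabolic_volume",
    "total_lesion_glycolysis",
    "discretize_voi",
    "build_glcm",
    "glcm_homogeneity",
    "glcm_entropy",
    "build_glrlm",
    "glrlm_sre",
    "glrlm_lre",
    "build_glszm",
    "glszm_lgze",
    "glszm_hgze",
    "texture_features",
    "extract_features",
    "aggregate_multifocal",
]

#: Radius (mm) of a 1 cm^3 sphere, used for SUVpeak: (3/(4*pi))^(1/3) * 10.
PEAK_RADIUS_MM = 6.2035

#: Texture matrices are meaningless on tiny VOIs; below this, features are NaN.
MIN_TEXTURE_VOXELS = 8

TEXTURE_NAMES = ("homogeneity", "entropy", "sre", "lre", "lgze", "hgze")

FEATURE_COLUMNS = [
    "patient_id",
    "scanner",
    "suv_max",
    "suv_mean",
    "suv_peak",
    "mtv_cm3",
    "tlg",
    "homogeneity",
    "entropy",
    "sre",
    "lre",
    "lgze",
    "hgze",
]

#: The 13 unique 3-D direction offsets (one representative per +/- pair).
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


@dataclass(frozen=True)
class DiscretizedVoi:
    """Integer gray levels (1..levels) on the VOI; 0 marks voxels outside it."""

    labels: np.ndarray
    levels: int

    @property
    def voxel_count(self) -> int:
        return int((self.labels > 0).sum())


@dataclass(frozen=True)
class FeatureVector:
    """The 11 per-tumor quantities plus the scanner batch label.

    Texture entries are NaN when the VOI is too small for texture matrices.
    """

    suv_max: float
    suv_mean: float
    suv_peak: float
    mtv_cm3: float
    tlg: float
    homogeneity: float
    entropy: float
    sre: float
    lre: float
    lgze: float
    hgze: float
    scanner: str = "unknown"

    def as_dict(self) -> dict[str, float | str]:
        return {
            "scanner": self.scanner,
            "suv_max": self.suv_max,
            "suv_mean": self.suv_mean,
            "suv_peak": self.suv_peak,
            "mtv_cm3": self.mtv_cm3,
            "tlg": self.tlg,
            "homogeneity": self.homogeneity,
            "entropy": self.entropy,
            "sre": self.sre,
            "lre": self.lre,
            "lgze": self.lgze,
            "hgze": self.hgze,
        }


# ---------------------------------------------------------------------------
# SUV statistics, MTV, TLG
# ---------------------------------------------------------------------------


def suv_peak(suv: SuvVolume, mask: LesionMask, radius_mm: float = PEAK_RADIUS_MM) -> float:
    """Mean SUV in a 1 cm^3 sphere centered on the hottest VOI voxel.

    Sphere membership is by voxel-center distance; voxels outside the mask
    (but inside the grid) contribute, per the usual peak convention.
    """
    grid = suv.grid
    masked = np.where(mask.mask, grid, -np.inf)
    center = np.unravel_index(int(np.argmax(masked)), grid.shape)
    spacing = np.asarray(suv.spacing, dtype=float)

    reach = np.ceil(radius_mm / spacing).astype(int)
    lo = [max(0, c - r) for c, r in zip(center, reach)]
    hi = [min(n, c + r + 1) for c, r, n in zip(center, reach, grid.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    idx = np.indices([b - a for a, b in zip(lo, hi)])
    d2 = np.zeros(idx.shape[1:])
    for ax in range(3):
        d2 += ((idx[ax] + lo[ax] - center[ax]) * spacing[ax]) ** 2
    inside = d2 <= radius_mm**2
    return float(grid[sl][inside].mean())


def suv_statistics(suv: SuvVolume, mask: LesionMask) -> tuple[float, float, float]:
    """(SUVmax, SUVmean, SUVpeak) over the lesion VOI."""
    values = suv.grid[mask.mask]
    if values.size == 0:
        raise ValidationError("empty mask")
    return float(values.max()), float(values.mean()), suv_peak(suv, mask)


def metabolic_volume(mask: LesionMask, spacing: tuple[float, float, float]) -> float:
    """MTV in cm^3: voxel count times voxel volume."""
    sx, sy, sz = spacing
    return mask.voxel_count * sx * sy * sz / 1000.0


def total_lesion_glycolysis(suv_mean: float, mtv_cm3: float) -> float:
    """TLG = SUVmean x MTV (SUV * cm^3)."""
    return suv_mean * mtv_cm3


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


def discretize_voi(
    suv: SuvVolume,
    mask: LesionMask,
    min_suv: float = 0.0,
    max_suv: float = 20.0,
    levels: int = 64,
) -> DiscretizedVoi:
    """Absolute discretization of the VOI into fixed-width SUV bins.

    ``level = 1 + floor((clip(SUV) - min) / (max - min) * levels)`` with values
    at or above ``max_suv`` mapped to the top level. Defaults give 64 bins of
    width 0.3125 SUV over 0–20.
    """
    if not max_suv > min_suv:
        raise ValidationError("max_suv must exceed min_suv")
    if levels < 2:
        raise ValidationError("need at least 2 gray levels")
    grid = suv.grid
    labels = np.zeros(grid.shape, dtype=np.int16)
    vals = np.clip(grid[mask.mask], min_suv, max_suv)
    lv = 1 + np.floor((vals - min_suv) / (max_suv - min_suv) * levels).astype(np.int64)
    labels[mask.mask] = np.minimum(lv, levels)
    return DiscretizedVoi(labels=labels, levels=levels)


# ---------------------------------------------------------------------------
# Gray-level co-occurrence matrix
# ---------------------------------------------------------------------------


def _offset_slices(shape, d):
    """Paired slices (a, b) such that arr[b] is arr[a] shifted by +d."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(0, n))
            dst.append(slice(0, n))
        elif step > 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def build_glcm(dvoi: DiscretizedVoi) -> np.ndarray:
    """Symmetric GLCM pooled over the 13 unit directions, normalized to sum 1.

    Only pairs with both voxels inside the VOI are counted.
    """
    labels = dvoi.labels
    L = dvoi.levels
    counts = np.zeros((L, L), dtype=np.int64)
    for d in DIRECTIONS_13:
        src, dst = _offset_slices(labels.shape, d)
        a = labels[src].ravel()
        b = labels[dst].ravel()
        ok = (a > 0) & (b > 0)
        np.add.at(counts, (a[ok] - 1, b[ok] - 1), 1)
    counts = counts + counts.T  # both orders → symmetric
    total = counts.sum()
    if total == 0:
        raise ValidationError("VOI has no voxel pairs; too small for a GLCM")
    return counts / total


def glcm_homogeneity(glcm: np.ndarray) -> float:
    """Sum of C(i,j) / (1 + |i - j|); 1.0 for a constant VOI."""
    i, j = np.indices(glcm.shape)
    return float((glcm / (1.0 + np.abs(i - j))).sum())


def glcm_entropy(glcm: np.ndarray) -> float:
    """-sum C log2 C in bits; zero cells contribute nothing."""
    p = glcm[glcm > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# Gray-level run-length matrix
# ---------------------------------------------------------------------------


def _in_bounds(coords: np.ndarray, shape) -> np.ndarray:
    ok = np.ones(len(coords), dtype=bool)
    for ax, n in enumerate(shape):
        ok &= (coords[:, ax] >= 0) & (coords[:, ax] < n)
    return ok


def build_glrlm(dvoi: DiscretizedVoi) -> np.ndarray:
    """GLRLM r(i, j): maximal equal-level runs pooled over the 13 directions.

    Row i is gray level i+1; column j is run length j+1. Runs break at VOI
    boundaries; every VOI voxel belongs to exactly one run per direction.
    """
    labels = dvoi.labels
    L = dvoi.levels
    run_records: list[tuple[int, int]] = []
    in_voi = labels > 0
    coords_all = np.argwhere(in_voi)
    for d in DIRECTIONS_13:
        dv = np.asarray(d)
        prev = coords_all - dv
        prev_ok = _in_bounds(prev, labels.shape)
        same_as_prev = np.zeros(len(coords_all), dtype=bool)
        if prev_ok.any():
            pi = prev[prev_ok]
            same_as_prev[prev_ok] = (
                labels[pi[:, 0], pi[:, 1], pi[:, 2]]
                == labels[coords_all[prev_ok, 0], coords_all[prev_ok, 1], coords_all[prev_ok, 2]]
            ) & (labels[pi[:, 0], pi[:, 1], pi[:, 2]] > 0)
        starts = coords_all[~same_as_prev]
        levels = labels[starts[:, 0], starts[:, 1], starts[:, 2]]
        lengths = np.ones(len(starts), dtype=np.int64)
        cur = starts.copy()
        active = np.ones(len(starts), dtype=bool)
        while active.any():
            nxt = cur[active] + dv
            ok = _in_bounds(nxt, labels.shape)
            cont = np.zeros(len(nxt), dtype=bool)
            if ok.any():
                ni = nxt[ok]
                cont[ok] = labels[ni[:, 0], ni[:, 1], ni[:, 2]] == levels[active][ok]
            idx = np.flatnonzero(active)
            stopped = idx[~cont]
            kept = idx[cont]
            active[stopped] = False
            lengths[kept] += 1
            cur[kept] = cur[kept] + dv
        run_records.append((levels, lengths))

    all_levels = np.concatenate([r[0] for r in run_records])
    all_lengths = np.concatenate([r[1] for r in run_records])
    if len(all_levels) == 0:
        raise ValidationError("VOI has no runs; empty discretized VOI")
    rmax = int(all_lengths.max())
    glrlm = np.zeros((L, rmax), dtype=np.int64)
    np.add.at(glrlm, (all_levels - 1, all_lengths - 1), 1)
    return glrlm


def glrlm_sre(glrlm: np.ndarray) -> float:
    """Short-run emphasis: (1/H) sum r(i,j) / j^2."""
    j = np.arange(1, glrlm.shape[1] + 1, dtype=float)
    total = glrlm.sum()
    return float((glrlm / j**2).sum() / total)


def glrlm_lre(glrlm: np.ndarray) -> float:
    """Long-run emphasis: (1/H) sum r(i,j) * j^2."""
    j = np.arange(1, glrlm.shape[1] + 1, dtype=float)
    total = glrlm.sum()
    return float((glrlm * j**2).sum() / total)


# ---------------------------------------------------------------------------
# Gray-level size-zone matrix
# ---------------------------------------------------------------------------


def build_glszm(dvoi: DiscretizedVoi) -> np.ndarray:
    """GLSZM z(i, j): 26-connected equal-level zones by level i+1 and size j+1."""
    labels = dvoi.labels
    L = dvoi.levels
    zone_levels: list[int] = []
    zone_sizes: list[int] = []
    for g in np.unique(labels[labels > 0]):
        comp, n = ndi.label(labels == g, structure=STRUCT_26)
        sizes = np.bincount(comp.ravel())[1:]
        zone_levels.extend([int(g)] * n)
        zone_sizes.extend(int(s) for s in sizes)
    if not zone_levels:
        raise ValidationError("VOI has no zones; empty discretized VOI")
    zmax = max(zone_sizes)
    glszm = np.zeros((L, zmax), dtype=np.int64)
    np.add.at(glszm, (np.asarray(zone_levels) - 1, np.asarray(zone_sizes) - 1), 1)
    return glszm


def glszm_lgze(glszm: np.ndarray) -> float:
    """Low-gray-level zone emphasis: (1/H) sum z(i,j) / i^2."""
    i = np.arange(1, glszm.shape[0] + 1, dtype=float)[:, None]
    total = glszm.sum()
    return float((glszm / i**2).sum() / total)


def glszm_hgze(glszm: np.ndarray) -> float:
    """High-gray-level zone emphasis: (1/H) sum z(i,j) * i^2."""
    i = np.arange(1, glszm.shape[0] + 1, dtype=float)[:, None]
    total = glszm.sum()
    return float((glszm * i**2).sum() / total)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def texture_features(
    suv: SuvVolume,
    mask: LesionMask,
    min_suv: float = 0.0,
    max_suv: float = 20.0,
    levels: int = 64,
) -> dict[str, float]:
    """The six texture scalars for one lesion, NaN if the VOI is too small."""
    if mask.voxel_count < MIN_TEXTURE_VOXELS:
        warnings.warn(
            f"VOI of {mask.voxel_count} voxels is below {MIN_TEXTURE_VOXELS}; "
            "texture features set to NaN",
            stacklevel=2,
        )
        return {name: float("nan") for name in TEXTURE_NAMES}
    dvoi = discretize_voi(suv, mask, min_suv=min_suv, max_suv=max_suv, levels=levels)
    glcm = build_glcm(dvoi)
    glrlm = build_glrlm(dvoi)
    glszm = build_glszm(dvoi)
    return {
        "homogeneity": glcm_homogeneity(glcm),
        "entropy": glcm_entropy(glcm),
        "sre": glrlm_sre(glrlm),
        "lre": glrlm_lre(glrlm),
        "lgze": glszm_lgze(glszm),
        "hgze": glszm_hgze(glszm),
    }


def _single_lesion_features(suv: SuvVolume, mask: LesionMask, scanner: str) -> FeatureVector:
    smax, smean, speak = suv_statistics(suv, mask)
    mtv = metabolic_volume(mask, suv.spacing)
    tex = texture_features(suv, mask)
    return FeatureVector(
        suv_max=smax,
        suv_mean=smean,
        suv_peak=speak,
        mtv_cm3=mtv,
        tlg=total_lesion_glycolysis(smean, mtv),
        scanner=scanner,
        **tex,
    )


def aggregate_multifocal(
    per_lesion: list[FeatureVector],
    index_textures: dict[str, float] | None = None,
) -> FeatureVector:
    """Combine per-lesion features into one tumor-level vector.

    MTV and TLG sum over lesions; SUVmean is the MTV-weighted mean (which
    preserves TLG = SUVmean x MTV exactly); SUVmax, SUVpeak and textures come
    from the index lesion (highest SUVmax, ties to larger MTV). Texture values
    may be overridden via ``index_textures``.
    """
    if not per_lesion:
        raise ValidationError("aggregate_multifocal needs at least one lesion")
    index = min(per_lesion, key=lambda f: (-f.suv_max, -f.mtv_cm3))
    if len(per_lesion) == 1 and index_textures is None:
        return index
    mtv = sum(f.mtv_cm3 for f in per_lesion)
    suv_mean = sum(f.mtv_cm3 * f.suv_mean for f in per_lesion) / mtv
    tex = index_textures if index_textures is not None else {
        name: getattr(index, name) for name in TEXTURE_NAMES
    }
    return FeatureVector(
        suv_max=index.suv_max,
        suv_mean=suv_mean,
        suv_peak=index.suv_peak,
        mtv_cm3=mtv,
        tlg=sum(f.tlg for f in per_lesion),
        scanner=index.scanner,
        **{name: tex[name] for name in TEXTURE_NAMES},
    )


def extract_features(
    suv: SuvVolume,
    masks: list[LesionMask] | None = None,
    roi=None,
    threshold: float = 2.5,
) -> FeatureVector:
    """Segment (if needed) and extract the tumor-level feature vector.

    Multifocal tumors are aggregated; textures are those of the index lesion.
    """
    if masks is None:
        masks = threshold_voi(suv, roi=roi, threshold=threshold)
    if not masks:
        raise ValidationError("no lesion at or above the SUV threshold")
    per_lesion = [_single_lesion_features(suv, m, suv.meta.scanner) for m in masks]
    index_mask = select_index_lesion(masks, suv)
    index_tex = texture_features(suv, index_mask)
    return aggregate_multifocal(per_lesion, index_textures=index_tex)
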