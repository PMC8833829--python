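"""Fixed-threshold tumor segmentation.

The lesion VOI is every voxel with SUV >= threshold (default 2.5, inclusive)
inside an axis-aligned region of interest, split into 26-connected components.
Components are ordered by descending SUVmax so the first element is the most
FDG-avid (index) lesion; ties go to the larger component, then the lower label.
An empty result is legal — it mirrors the exclusion of tumors whose uptake
never reaches the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .imaging import SuvVolume, ValidationError

__all__ = ["RoiBox", "LesionMask", "threshold_voi", "select_index_lesion", "SUV_THRESHOLD"]

SUV_THRESHOLD = 2.5

#: 3x3x3 all-ones structuring element = 26-connectivity.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned box in voxel indices, half-open on the upper bound."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        lower = tuple(int(v) for v in self.lower)
        upper = tuple(int(v) for v in self.upper)
        if len(lower) != 3 or len(upper) != 3:
            raise ValidationError("RoiBox corners must be 3-D voxel indices")
        if any(lo < 0 for lo in lower) or any(hi <= lo for lo, hi in zip(lower, upper)):
            raise ValidationError(f"empty or invalid RoiBox: {lower}..{upper}")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    def validate_against(self, shape: tuple[int, ...]) -> None:
        if any(hi > n for hi, n in zip(self.upper, shape)):
            raise ValidationError(f"RoiBox {self.lower}..{self.upper} exceeds grid {shape}")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.lower, self.upper))


@dataclass(frozen=True)
class LesionMask:
    """One connected lesion component, on the full volume grid."""

    mask: np.ndarray
    component_id: int
    voxel_count: int

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        count = int(mask.sum())
        if count < 1:
            raise ValidationError("LesionMask must contain at least one voxel")
        if count != self.voxel_count:
            raise ValidationError("voxel_count does not match the mask")
        object.__setattr__(self, "mask", mask)


def threshold_voi(
    suv: SuvVolume,
    roi: RoiBox | None = None,
    threshold: float = SUV_THRESHOLD,
) -> list[LesionMask]:
    """Segment the VOI at a fixed SUV threshold inside ``roi``.

    Returns the 26-connected components of ``{SUV >= threshold} ∩ roi`` as
    full-grid binary masks sorted by descending SUVmax (ties: larger component,
    then lower component id). An empty list means no voxel qualified.
    """
    grid = suv.grid
    if roi is None:
        roi = RoiBox((0, 0, 0), grid.shape)
    roi.validate_against(grid.shape)

    selected = np.zeros(grid.shape, dtype=bool)
    sl = roi.slices()
    selected[sl] = grid[sl] >= threshold
    if not selected.any():
        return []

    labels, n = ndi.label(selected, structure=STRUCT_26)
    masks = []
    for comp_id in range(1, n + 1):
        mask = labels == comp_id
        masks.append(LesionMask(mask=mask, component_id=comp_id, voxel_count=int(mask.sum())))
    masks.sort(key=lambda m: (-float(grid[m.mask].max()), -m.voxel_count, m.component_id))
    return masks


def select_index_lesion(masks: list[LesionMask], suv: SuvVolume) -> LesionMask:
    """The most FDG-avid lesion: highest SUVmax, ties to larger count then lower id."""
    if not masks:
        raise ValidationError("cannot select an index lesion from an empty list")
    return min(
        masks,
        key=lambda m: (-float(suv.grid[m.mask].max()), -m.voxel_count, m.component_id),
    )
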