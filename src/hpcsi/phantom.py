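"""Digital head phantom for the ferret-scale FID-CSI simulation.

The phantom is a labeled 2-D compartment map on the native acquisition
grid: an elliptical brain split into ipsilateral/contralateral
hemispheres, a scalp-muscle ring around the skull, a midline vascular
structure (sagittal sinus / circle of Willis analogue) carrying a strong
pyruvate signal, and — for injured subjects — a focal lesion inside the
ipsilateral hemisphere whose oxidative conversion rate (k_PB) is reduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import KineticParams

__all__ = [
    "LABELS",
    "PhantomSpec",
    "Phantom",
    "build_phantom",
    "default_kinetics",
    "roi_masks",
]

LABELS = {
    "background": 0,
    "brain_ipsi": 1,
    "brain_contra": 2,
    "lesion": 3,
    "muscle": 4,
    "vessel": 5,
}

_BRAIN_SEMI_AXES_MM = (17.0, 13.0)  # (x, y)
_MUSCLE_OUTER_SCALE = 1.45
_VESSEL_HALFWIDTH_MM = 2.0
_VESSEL_Y_MM = (9.0, 14.0)


def default_kinetics(lesion_kpb_scale: float = 0.5) -> dict[int, KineticParams]:
    """Per-label kinetic parameters.

    Healthy brain rates give single-shot signal ratios in the range seen
    in vivo (Lac/Pyr ~ 0.2, Bic/Pyr ~ 0.07 at a 30-46 s read-out); the
    lesion keeps glycolytic conversion but has k_PB scaled down
    (mitochondrial/PDH dysfunction); muscle produces most of the alanine;
    the vessel is a high-pyruvate, non-converting pool.
    """
    brain = KineticParams(k_pl=0.021, k_pb=0.0078, k_pa=0.0018)
    lesion = replace(brain, k_pb=brain.k_pb * lesion_kpb_scale)
    muscle = KineticParams(k_pl=0.013, k_pb=0.002, k_pa=0.013)
    vessel = KineticParams(perfusion_scale=3.0)
    return {
        LABELS["brain_ipsi"]: brain,
        LABELS["brain_contra"]: brain,
        LABELS["lesion"]: lesion,
        LABELS["muscle"]: muscle,
        LABELS["vessel"]: vessel,
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric/kinetic description from which a phantom is built."""

    matrix: int = 16
    fov_mm: float = 60.0
    injured: bool = False
    lesion_side: str = "left"
    lesion_center_mm: tuple[float, float] = (8.0, 3.0)  # (|x|, y), x sign from side
    lesion_radius_mm: float = 7.0
    lesion_kpb_scale: float = 0.5
    kinetics_by_label: dict[int, KineticParams] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.matrix < 8:
            raise ValueError("phantom matrix must be >= 8")
        if self.lesion_side not in ("left", "right"):
            raise ValueError("lesion_side must be 'left' or 'right'")
        if self.lesion_radius_mm <= 0:
            raise ValueError("lesion radius must be positive")


@dataclass(frozen=True)
class Phantom:
    """Labeled compartment map plus per-compartment kinetics."""

    label_map: np.ndarray  # int, (matrix, matrix), indexed [y, x]
    kinetics_by_label: dict[int, KineticParams]
    grid_fov_mm: float
    spec: PhantomSpec

    def __post_init__(self) -> None:
        present = set(np.unique(self.label_map)) - {0}
        missing = present - set(self.kinetics_by_label)
        if missing:
            raise ValueError(f"labels without kinetics: {sorted(missing)}")

    @property
    def voxel_mm(self) -> float:
        return self.grid_fov_mm / self.label_map.shape[0]


def _grid_mm(matrix: int, fov_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-center coordinates (y, x) in mm, symmetric about the origin."""
    c = (np.arange(matrix) + 0.5 - matrix / 2) * (fov_mm / matrix)
    return np.meshgrid(c, c, indexing="ij")  # (Y, X)


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministically rasterize *spec* onto the acquisition grid."""
    y, x = _grid_mm(spec.matrix, spec.fov_mm)
    ax, ay = _BRAIN_SEMI_AXES_MM
    r_brain = np.sqrt((x / ax) ** 2 + (y / ay) ** 2)

    labels = np.zeros((spec.matrix, spec.matrix), dtype=np.int64)
    labels[(r_brain > 1.0) & (r_brain <= _MUSCLE_OUTER_SCALE)] = LABELS["muscle"]
    brain = r_brain <= 1.0
    labels[brain & (x < 0)] = LABELS["brain_ipsi" if spec.lesion_side == "left" else "brain_contra"]
    labels[brain & (x > 0)] = LABELS["brain_contra" if spec.lesion_side == "left" else "brain_ipsi"]

    vessel = (
        brain
        & (np.abs(x) <= _VESSEL_HALFWIDTH_MM)
        & (y >= _VESSEL_Y_MM[0])
        & (y <= _VESSEL_Y_MM[1])
    )
    labels[vessel] = LABELS["vessel"]

    cx = -spec.lesion_center_mm[0] if spec.lesion_side == "left" else spec.lesion_center_mm[0]
    cy = spec.lesion_center_mm[1]
    if spec.injured:
        if abs(cx) - spec.lesion_radius_mm < 0:
            raise ValueError("lesion extends across the midline")
        edge = np.sqrt(((abs(cx) + spec.lesion_radius_mm) / ax) ** 2 + (cy / ay) ** 2)
        if edge > 1.0:
            raise ValueError("lesion extends outside the brain ellipse")
        lesion = brain & ((x - cx) ** 2 + (y - cy) ** 2 <= spec.lesion_radius_mm**2)
        labels[lesion & ~vessel] = LABELS["lesion"]

    kin = spec.kinetics_by_label or default_kinetics(spec.lesion_kpb_scale)
    return Phantom(labels, dict(kin), spec.fov_mm, spec)


def roi_masks(phantom: Phantom, upsample: int = 1) -> dict[str, np.ndarray]:
    """Mirrored analysis ROIs derived from the phantom geometry.

    ``ipsi`` is a disc at the (actual or would-be) lesion site clipped to
    brain tissue; ``contra`` is its left-right mirror; ``muscle`` and
    ``brain`` follow the labels.  *upsample* replicates voxels to match a
    zero-filled reconstruction grid (e.g. 2 for 16 -> 32).
    """
    spec = phantom.spec
    m = spec.matrix
    y, x = _grid_mm(m, phantom.grid_fov_mm)
    ax, ay = _BRAIN_SEMI_AXES_MM
    brain = np.sqrt((x / ax) ** 2 + (y / ay) ** 2) <= 1.0

    cx = -spec.lesion_center_mm[0] if spec.lesion_side == "left" else spec.lesion_center_mm[0]
    cy = spec.lesion_center_mm[1]
    disc_i = brain & ((x - cx) ** 2 + (y - cy) ** 2 <= spec.lesion_radius_mm**2)
    disc_c = brain & ((x + cx) ** 2 + (y - cy) ** 2 <= spec.lesion_radius_mm**2)

    masks = {
        "ipsi": disc_i,
        "contra": disc_c,
        "muscle": phantom.label_map == LABELS["muscle"],
        "brain": brain,
    }
    if upsample > 1:
        ones = np.ones((upsample, upsample), dtype=bool)
        masks = {k: np.kron(v, ones) for k, v in masks.items()}
    for name, mask in masks.items():
        if not mask.any():
            raise ValueError(f"derived ROI {name!r} is empty")
    assert not (masks["ipsi"] & masks["contra"]).any()
    return masks
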