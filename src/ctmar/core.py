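"""Core containers shared across the toolkit.

The universal currency is the :class:`CTSlice`: a 2-D raster of Hounsfield
units (water = 0, air = -1000) with physical pixel spacing.  Projection data
live in :class:`Sinogram` objects, tagged as line integrals or photon counts
so the two representations are never mixed silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CTSlice",
    "TissueMaskSet",
    "Sinogram",
    "PairedSample",
    "LINE_INTEGRAL",
    "PHOTON_COUNT",
]

LINE_INTEGRAL = "line_integral"
PHOTON_COUNT = "photon_count"


@dataclass
class CTSlice:
    """A single axial CT slice in Hounsfield units.

    Parameters
    ----------
    values : ndarray
        2-D float raster of HU values.  Finite values only.
    pixel_spacing : float
        In-plane pixel size in millimetres (isotropic).
    thickness : float
        Slice thickness in millimetres.
    id : str
        Free-form identifier (patient/slice naming).
    meta : dict
        Provenance: seeds, simulation config, clipping records.
    """

    values: np.ndarray
    pixel_spacing: float = 0.7
    thickness: float = 3.0
    id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("CTSlice expects a 2-D raster, got shape "
                             f"{self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CTSlice values must be finite")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive (mm)")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def copy(self, **overrides) -> "CTSlice":
        kw = dict(values=self.values.copy(), pixel_spacing=self.pixel_spacing,
                  thickness=self.thickness, id=self.id, meta=dict(self.meta))
        kw.update(overrides)
        return CTSlice(**kw)


@dataclass
class TissueMaskSet:
    """Mutually exclusive binary masks partitioning a slice into tissue classes.

    ``lung | water_equiv | bone | metal | background`` covers every pixel;
    the masks are pairwise disjoint by construction of the segmentation.
    """

    lung: np.ndarray
    water_equiv: np.ndarray
    bone: np.ndarray
    metal: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.all_masks().values()}
        if len(shapes) != 1:
            raise ValueError("tissue masks must be congruent")
        total = sum(m.astype(np.int64) for m in self.all_masks().values())
        if total.min() < 1 or total.max() > 1:
            raise ValueError("tissue masks must partition the image "
                             "(pairwise disjoint, jointly covering)")

    def all_masks(self) -> dict:
        return {"lung": self.lung, "water_equiv": self.water_equiv,
                "bone": self.bone, "metal": self.metal,
                "background": self.background}


@dataclass
class Sinogram:
    """Parallel-beam projection data, (n_views, n_detectors).

    ``kind`` distinguishes dimensionless line integrals (optical depth) from
    realized photon counts; operations check the tag instead of guessing.
    """

    data: np.ndarray
    angles_deg: np.ndarray
    detector_spacing: float  # mm
    kind: str = LINE_INTEGRAL
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("sinogram data must be 2-D (views x detectors)")
        if self.data.shape[0] != self.angles_deg.size:
            raise ValueError("number of views must match number of angles")
        if self.kind not in (LINE_INTEGRAL, PHOTON_COUNT):
            raise ValueError(f"unknown sinogram kind: {self.kind!r}")

    @property
    def n_views(self) -> int:
        return self.data.shape[0]

    @property
    def n_detectors(self) -> int:
        return self.data.shape[1]


@dataclass
class PairedSample:
    """An aligned (CT_ref, CT_art) pair — the unit of supervision/evaluation."""

    ref: CTSlice
    art: CTSlice
    cor: Optional[CTSlice] = None
    patient_id: str = ""
    slice_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref.shape != self.art.shape:
            raise ValueError("ref and art slices must be congruent")
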