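"""Synthetic thorax phantom and ultrasound-transducer generator.

Every downstream stage (artifact simulation, network training, evaluation)
is exercised on these seeded phantoms, so no external dataset is needed.
Anatomy is deliberately simple — ellipse-composited body, lungs, heart,
vertebra and ribs — because the simulator and the network only need
class-correct HU structure (soft tissue ~40 HU, lung ~-700 HU, bone ~700 HU,
air -1000 HU), not anatomical realism.

The transducer is a rectangular plastic housing with an embedded metal bar
standing in for the piezoceramic stack; the 60 mm core width matches a
linear volume array probe, and the core HU (>= 3000) guarantees it is
recoverable by the 2000 HU metal-extraction threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import CTSlice

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "TransducerSpec",
    "TransducerOverlay",
    "Pose",
    "make_thorax_phantom",
    "make_transducer",
    "insert_transducer",
    "anterior_pose",
    "LABELS",
]

# label-map codes
LABELS = {"background": 0, "soft": 1, "lung": 2, "heart": 3, "bone": 4}


@dataclass(frozen=True)
class Ellipse:
    """Ellipse in pixel coordinates: centre, semi-axes, rotation (deg)."""
    cx: float
    cy: float
    a: float
    b: float
    rot_deg: float = 0.0

    def mask(self, n: int) -> np.ndarray:
        yy, xx = np.mgrid[0:n, 0:n]
        th = np.deg2rad(self.rot_deg)
        dx, dy = xx - self.cx, yy - self.cy
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0

    def inside_image(self, n: int) -> bool:
        th = np.deg2rad(self.rot_deg)
        half_w = np.hypot(self.a * np.cos(th), self.b * np.sin(th))
        half_h = np.hypot(self.a * np.sin(th), self.b * np.cos(th))
        return (self.cx - half_w >= 0 and self.cx + half_w <= n - 1
                and self.cy - half_h >= 0 and self.cy + half_h <= n - 1)


def _default_geometry(n: int) -> dict:
    ribs = []
    body_cx, body_cy = 0.5 * n, 0.55 * n
    for ang in np.linspace(25, 155, 4):
        for sign in (+1, -1):
            a = np.deg2rad(ang) * sign
            rx = body_cx + 0.92 * 0.44 * n * np.sin(a)
            ry = body_cy - 0.92 * 0.34 * n * np.cos(a)
            ribs.append(Ellipse(rx, ry, 0.018 * n, 0.008 * n,
                                rot_deg=float(np.rad2deg(a)) + 90.0))
    return {
        "body": [Ellipse(body_cx, body_cy, 0.44 * n, 0.34 * n)],
        "lung": [Ellipse(0.32 * n, 0.52 * n, 0.13 * n, 0.22 * n, -12.0),
                 Ellipse(0.68 * n, 0.52 * n, 0.13 * n, 0.22 * n, 12.0)],
        "heart": [Ellipse(0.46 * n, 0.58 * n, 0.10 * n, 0.115 * n, 20.0)],
        "bone": [Ellipse(0.5 * n, 0.82 * n, 0.045 * n, 0.04 * n)] + ribs,
    }


@dataclass
class PhantomSpec:
    """Parameters of a synthetic thorax slice.

    ``pixel_spacing`` defaults to 0.7 mm at 512 px (a ~36 cm adult-thorax
    field of view); :meth:`default` rescales the spacing for other sizes so
    physical extents are preserved.  ``jitter_frac`` controls the anatomical
    variation across "patients" (relative jitter of ellipse centres/axes).
    """

    image_size: int = 512
    pixel_spacing: float = 0.7
    ellipses: dict = field(default_factory=dict)
    tissue_hu: dict = field(default_factory=lambda: {
        "soft": 40.0, "lung": -700.0, "heart": 35.0, "bone": 700.0,
        "background": -1000.0})
    texture_sigma_hu: float = 10.0
    edge_sigma_px: float = 0.8
    jitter_frac: float = 0.03
    jitter_seed: int = 0

    @classmethod
    def default(cls, image_size: int = 512, **overrides) -> "PhantomSpec":
        spacing = overrides.pop("pixel_spacing", 0.7 * 512 / image_size)
        spec = cls(image_size=image_size, pixel_spacing=spacing, **overrides)
        if not spec.ellipses:
            spec.ellipses = _default_geometry(image_size)
        return spec

    def validate(self) -> None:
        if not self.ellipses:
            raise ValueError("PhantomSpec has no ellipses")
        for region, elists in self.ellipses.items():
            for e in elists:
                if not e.inside_image(self.image_size):
                    raise ValueError(
                        f"{region} ellipse at ({e.cx:.1f},{e.cy:.1f}) with "
                        f"semi-axes ({e.a:.1f},{e.b:.1f}) extends outside the "
                        f"{self.image_size}x{self.image_size} image")
        for region, hu in self.tissue_hu.items():
            if not (-1024.0 <= hu <= 1500.0):
                raise ValueError(
                    f"tissue HU for {region!r} = {hu} outside [-1024, 1500]")


def _jitter(e: Ellipse, rng: np.random.Generator, frac: float,
            n: int) -> Ellipse:
    return Ellipse(
        cx=e.cx + rng.normal(0.0, 0.5 * frac * n),
        cy=e.cy + rng.normal(0.0, 0.5 * frac * n),
        a=e.a * (1.0 + rng.normal(0.0, frac)),
        b=e.b * (1.0 + rng.normal(0.0, frac)),
        rot_deg=e.rot_deg + rng.normal(0.0, 60.0 * frac),
    )


def _fit_inside(e: Ellipse, n: int, region: str) -> Ellipse:
    th = np.deg2rad(e.rot_deg)
    half_w = np.hypot(e.a * np.cos(th), e.b * np.sin(th))
    half_h = np.hypot(e.a * np.sin(th), e.b * np.cos(th))
    if 2 * half_w > n - 1 or 2 * half_h > n - 1:
        raise ValueError(f"jittered {region} ellipse larger than the image; "
                         "reduce jitter_frac or shrink the anatomy")
    return replace(e, cx=float(np.clip(e.cx, half_w, n - 1 - half_w)),
                   cy=float(np.clip(e.cy, half_h, n - 1 - half_h)))


def make_thorax_phantom(spec: PhantomSpec, seed: int = 0
                        ) -> tuple[CTSlice, np.ndarray]:
    """Generate one seeded thorax slice and its region label map.

    Returns the HU slice (with optional Gaussian texture of
    ``spec.texture_sigma_hu`` inside the body) and a uint8 label map coded
    per :data:`LABELS`.  Identical ``(spec, seed)`` give bit-identical
    output; seeds vary the anatomy through the configured jitter.
    """
    spec.validate()
    n = spec.image_size
    rng = np.random.default_rng([int(spec.jitter_seed), int(seed)])

    geo = {region: [_jitter(e, rng, spec.jitter_frac, n) for e in es]
           for region, es in spec.ellipses.items()}
    # jitter may nudge an ellipse against the canvas; re-centre it inside
    # (axes preserved) so every seed yields a valid phantom
    for region, es in geo.items():
        for i, e in enumerate(es):
            if not e.inside_image(n):
                es[i] = _fit_inside(e, n, region)

    label = np.zeros((n, n), dtype=np.uint8)
    for region in ("body", "lung", "heart", "bone"):
        code = LABELS["soft"] if region == "body" else LABELS[region]
        for e in geo.get(region, []):
            label[e.mask(n)] = code

    hu = np.full((n, n), spec.tissue_hu["background"], dtype=np.float64)
    for region, code in (("soft", 1), ("lung", 2), ("heart", 3), ("bone", 4)):
        hu[label == code] = spec.tissue_hu[region]

    if spec.texture_sigma_hu > 0:
        noise = rng.normal(0.0, spec.texture_sigma_hu, size=(n, n))
        hu = np.where(label > 0, hu + noise, hu)

    # Band-limit the raster (label map stays crisp): clinical reference
    # slices are reconstructions and carry no sub-pixel-sharp edges.
    if spec.edge_sigma_px > 0:
        hu = ndimage.gaussian_filter(hu, spec.edge_sigma_px)

    ct = CTSlice(values=hu, pixel_spacing=spec.pixel_spacing,
                 id=f"phantom-{seed}",
                 meta={"seed": int(seed), "jitter_seed": int(spec.jitter_seed),
                       "texture_sigma_hu": spec.texture_sigma_hu})
    return ct, label


@dataclass
class TransducerSpec:
    """Geometry and HU of the synthetic ultrasound probe.

    ``footprint_width`` is the metal-core width in mm (default 60, a linear
    volume array probe); ``metal_hu`` must be >= 2000 or the core would be
    invisible to the metal-extraction threshold.  The non-metal housing has
    no quantitative description in the source material; its HU and extent
    are free parameters with plastic-like defaults.
    """

    footprint_width: float = 60.0     # mm, metal core width
    metal_thickness: float = 6.0      # mm
    metal_hu: float = 3000.0
    housing_width: float = 72.0       # mm
    housing_height: float = 22.0      # mm
    housing_hu: float = -50.0

    def validate(self) -> None:
        if self.footprint_width <= 0:
            raise ValueError("footprint_width must be positive")
        if self.metal_hu < 2000.0:
            raise ValueError(
                f"metal_hu = {self.metal_hu} < 2000 HU would be invisible to "
                "the metal-extraction threshold")
        if not (self.housing_width >= self.footprint_width
                and self.housing_height >= self.metal_thickness):
            raise ValueError("housing must enclose the metal core")


@dataclass
class TransducerOverlay:
    """Full-canvas overlay raster with support and metal masks."""
    overlay: np.ndarray   # HU where support, housing_hu elsewhere (for interp)
    support: np.ndarray   # bool
    metal: np.ndarray     # bool
    pixel_spacing: float


@dataclass(frozen=True)
class Pose:
    """Rigid placement: rotation about image centre (deg) then translation (px)."""
    angle_deg: float = 0.0
    dx: float = 0.0
    dy: float = 0.0


def make_transducer(spec: TransducerSpec, image_size: int,
                    pixel_spacing: float) -> TransducerOverlay:
    """Rasterize the probe at the canvas centre (pose applied at insertion).

    The metal core spans ``ceil(footprint_width / pixel_spacing)`` pixel
    columns; the metal mask is a filled rectangle, hence 4-connected.
    """
    spec.validate()
    n = image_size

    def _rect(w_mm: float, h_mm: float) -> np.ndarray:
        w = int(np.ceil(w_mm / pixel_spacing))
        h = int(np.ceil(h_mm / pixel_spacing))
        m = np.zeros((n, n), dtype=bool)
        r0 = n // 2 - h // 2
        c0 = n // 2 - w // 2
        if r0 < 0 or c0 < 0 or r0 + h > n or c0 + w > n:
            raise ValueError("transducer does not fit the canvas")
        m[r0:r0 + h, c0:c0 + w] = True
        return m

    support = _rect(spec.housing_width, spec.housing_height)
    metal = _rect(spec.footprint_width, spec.metal_thickness)
    overlay = np.full((n, n), spec.housing_hu, dtype=np.float64)
    overlay[metal] = spec.metal_hu
    return TransducerOverlay(overlay=overlay, support=support, metal=metal,
                             pixel_spacing=pixel_spacing)


def _rigid_matrix(pose: Pose, n: int) -> tuple[np.ndarray, np.ndarray]:
    # scipy affine_transform maps output coords -> input coords (inverse map)
    th = np.deg2rad(pose.angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    center = np.array([(n - 1) / 2.0, (n - 1) / 2.0])
    shift = np.array([pose.dy, pose.dx])
    # forward: out = R (in - c) + c + shift  ->  in = R^T (out - c - shift) + c
    offset = center - rot.T @ (center + shift)
    return rot.T, offset


def insert_transducer(ct: CTSlice, overlay: TransducerOverlay, pose: Pose,
                      label_map: np.ndarray | None = None
                      ) -> tuple[CTSlice, np.ndarray]:
    """Composite the probe onto a slice under a rigid pose.

    HU values are resampled linearly; the support and metal masks use
    nearest-neighbour resampling so they stay binary.  Outside the
    transformed support the slice is untouched.  If the pose pushes the
    probe across the image edge a warning is raised and the overlay is hard
    clipped.  If a label map is supplied, metal overlapping the heart region
    raises an error.
    """
    n = ct.shape[0]
    mat, offset = _rigid_matrix(pose, n)

    # bounding-box corner check for clipping
    rows, cols = np.nonzero(overlay.support)
    fr = np.array([[np.cos(np.deg2rad(pose.angle_deg)),
                    -np.sin(np.deg2rad(pose.angle_deg))],
                   [np.sin(np.deg2rad(pose.angle_deg)),
                    np.cos(np.deg2rad(pose.angle_deg))]])
    c = (n - 1) / 2.0
    corners = np.array([[rows.min(), cols.min()], [rows.min(), cols.max()],
                        [rows.max(), cols.min()], [rows.max(), cols.max()]],
                       dtype=np.float64)
    moved = (fr @ (corners - c).T).T + c + np.array([pose.dy, pose.dx])
    if moved.min() < -0.5 or moved.max() > n - 0.5:
        warnings.warn("transducer pose clips the image edge; overlay is "
                      "hard-clipped", stacklevel=2)

    if pose.angle_deg == 0.0 and pose.dx == 0.0 and pose.dy == 0.0:
        ov_t, sup_t, met_t = overlay.overlay, overlay.support, overlay.metal
    else:
        ov_t = ndimage.affine_transform(overlay.overlay, mat, offset=offset,
                                        order=1, mode="constant",
                                        cval=overlay.overlay[0, 0])
        sup_t = ndimage.affine_transform(overlay.support.astype(np.uint8),
                                         mat, offset=offset, order=0,
                                         mode="constant", cval=0).astype(bool)
        met_t = ndimage.affine_transform(overlay.metal.astype(np.uint8),
                                         mat, offset=offset, order=0,
                                         mode="constant", cval=0).astype(bool)

    if label_map is not None and np.any(met_t & (label_map == LABELS["heart"])):
        raise ValueError("transducer metal overlaps the heart region")

    out = np.where(sup_t, ov_t, ct.values)
    new = ct.copy(values=out)
    new.meta = dict(ct.meta, transducer_pose=(pose.angle_deg, pose.dx, pose.dy))
    return new, met_t


def anterior_pose(phantom_spec: PhantomSpec, trans_spec: TransducerSpec,
                  angle_deg: float = 0.0, gap_mm: float = 1.0) -> Pose:
    """Pose placing the probe face on the anterior (top) body surface."""
    n = phantom_spec.image_size
    body = phantom_spec.ellipses["body"][0]
    top_row = body.cy - body.b
    h_px = np.ceil(trans_spec.housing_height / phantom_spec.pixel_spacing)
    gap_px = gap_mm / phantom_spec.pixel_spacing
    target_cy = top_row - gap_px - h_px / 2.0
    return Pose(angle_deg=angle_deg, dx=body.cx - (n - 1) / 2.0,
                dy=target_cy - (n - 1) / 2.0)
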