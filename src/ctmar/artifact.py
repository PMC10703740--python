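"""Physics-based metal-artifact simulation.

From a clean HU slice plus a metal mask this module manufactures the
artifacted twin: tissues are segmented by HU thresholds, converted to linear
attenuation per energy bin, forward projected, combined into polychromatic
photon counts with Poisson noise, log-converted with a photon-starvation
floor, and reconstructed by filtered back projection.  Beam hardening (the
polychromatic spectrum) and photon starvation (the count floor behind thick
metal) are the two artifact mechanisms; with a monochromatic spectrum, no
noise and no metal the pipeline is close to an identity up to the
segmentation-based attenuation model.

The energy loop is cheap because the attenuation raster factorizes:
``mu_E = rho * (mu/rho)_class(E)``, so one density sinogram per tissue class
is projected once and the per-energy line integrals are linear combinations
with the class mass-attenuation coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .attenuation import (AttenuationTable, DEFAULT_TABLE, Spectrum,
                          effective_energy, filtered_kramers_spectrum)
from .core import (CTSlice, LINE_INTEGRAL, PHOTON_COUNT, Sinogram,
                   TissueMaskSet)
from .projection import (default_angles, forward_project, mu_to_hu,
                         reconstruct_fbp)

__all__ = [
    "extract_metal",
    "segment_tissues",
    "hu_to_density",
    "hu_to_mu",
    "polychromatic_counts",
    "counts_to_line_integrals",
    "SimConfig",
    "simulate_artifact",
    "density_map",
    "starvation_path_cm",
    "metal_crossing_mask",
    "streak_index",
    "MASK_MATERIAL",
]

# tissue-class -> attenuation-table material
MASK_MATERIAL = {"lung": "lung", "water_equiv": "water",
                 "bone": "cortical_bone", "metal": "pzt_metal"}


def extract_metal(ct: CTSlice, threshold_hu: float = 2000.0
                  ) -> tuple[np.ndarray, int]:
    """Threshold-based metal extraction (inclusive comparator).

    Returns the binary mask ``ct >= threshold_hu`` and its pixel count; an
    empty mask is a legal result.
    """
    mask = ct.values >= threshold_hu
    return mask, int(mask.sum())


def segment_tissues(ct: CTSlice,
                    lung_max: float = -300.0,
                    bone_min: float = 150.0,
                    metal_min: float = 2000.0,
                    body_air_hu: float = -900.0) -> TissueMaskSet:
    """Threshold segmentation into lung / water-equivalent / bone / metal.

    Background is the air region below ``body_air_hu`` that is connected to
    the image border; enclosed air (e.g. lung) stays inside the body
    support.  The three thresholds must be strictly increasing.
    """
    if not (lung_max < bone_min < metal_min):
        raise ValueError("thresholds must satisfy lung_max < bone_min < "
                         f"metal_min, got ({lung_max}, {bone_min}, {metal_min})")
    v = ct.values
    air = v < body_air_hu
    lab, _ = ndimage.label(air)
    border_labels = np.unique(np.concatenate([
        lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]))
    border_labels = border_labels[border_labels > 0]
    background = np.isin(lab, border_labels)

    inside = ~background
    metal = inside & (v >= metal_min)
    bone = inside & (v >= bone_min) & (v < metal_min)
    lung = inside & (v < lung_max)
    water = inside & (v >= lung_max) & (v < bone_min)
    return TissueMaskSet(lung=lung, water_equiv=water, bone=bone,
                         metal=metal, background=background)


def hu_to_density(hu: np.ndarray) -> np.ndarray:
    """Piecewise-linear HU -> mass density (g/cm^3) calibration.

    -1000 HU -> 0.0, 0 HU -> 1.0, 1000 HU -> 1.6, clamped outside; metal
    pixels are handled separately with the metal reference density.
    """
    hu = np.asarray(hu, dtype=np.float64)
    lo = 1.0 + hu / 1000.0
    hi = 1.0 + 0.6 * hu / 1000.0
    rho = np.where(hu <= 0.0, lo, hi)
    return np.clip(rho, 0.0, 1.6)


def density_map(ct: CTSlice, masks: TissueMaskSet,
                table: AttenuationTable | None = None,
                model: str = "consistent",
                e_ref_keV: float = 70.0) -> np.ndarray:
    """Per-pixel mass density (g/cm^3) from HU and tissue class.

    ``model="consistent"`` (default) chooses each tissue pixel's density so
    that ``rho * (mu/rho)_class(e_ref)`` reproduces the pixel's HU exactly at
    the reference energy — the artifact-free simulation limit then returns
    the reference slice, and beam hardening still arises from the class
    energy dependence.  ``model="ramp"`` uses the generic piecewise-linear
    HU->density calibration (:func:`hu_to_density`) for every tissue class.
    Metal pixels always use the piezoceramic reference density (their HU is
    saturated and carries no density information).
    """
    table = table or DEFAULT_TABLE
    if model == "ramp":
        rho = hu_to_density(ct.values)
    elif model == "consistent":
        mu_w_ref = float(table.mu("water", e_ref_keV))
        mu_target = np.clip(1.0 + ct.values / 1000.0, 0.0, None) * mu_w_ref
        rho = np.zeros_like(ct.values)
        for name, material in MASK_MATERIAL.items():
            if name == "metal":
                continue
            m = getattr(masks, name)
            if np.any(m):
                rho[m] = mu_target[m] / float(
                    table.mu_over_rho(material, e_ref_keV))
    else:
        raise ValueError(f"unknown density model {model!r}")
    rho[masks.background] = 0.0
    rho[masks.metal] = table.density("pzt_metal")
    return rho


def hu_to_mu(ct: CTSlice, masks: TissueMaskSet,
             table: AttenuationTable | None = None,
             energy_keV: float = 70.0,
             density_model: str = "consistent",
             e_ref_keV: float = 70.0) -> np.ndarray:
    """Linear attenuation raster (1/cm) at one energy.

    Per pixel: ``mu = rho * (mu/rho)_class(E)`` with the class given by the
    pixel's mask and the density from :func:`density_map`; background is air
    (mu = 0).
    """
    table = table or DEFAULT_TABLE
    rho = density_map(ct, masks, table, density_model, e_ref_keV)
    mu = np.zeros_like(rho)
    for name, material in MASK_MATERIAL.items():
        m = getattr(masks, name)
        if np.any(m):
            mu[m] = rho[m] * float(table.mu_over_rho(material, energy_keV))
    return mu


def polychromatic_counts(line_integrals_by_energy: list[Sinogram],
                         spectrum: Spectrum,
                         seed: int | None = None,
                         noise: bool = True
                         ) -> tuple[Sinogram, Sinogram]:
    """Combine per-energy optical depths into detected photon counts.

    Expected counts are ``i0 * sum_E w_E exp(-P_E)``; realized counts are
    Poisson draws with the given seed.  Returns ``(realized, expected)``;
    with ``noise=False`` the realized counts equal the expectation.
    """
    if len(line_integrals_by_energy) != spectrum.n_bins:
        raise ValueError("need one line-integral sinogram per spectrum bin")
    lam = None
    proto = line_integrals_by_energy[0]
    for w, sino in zip(spectrum.weights, line_integrals_by_energy):
        if sino.kind != LINE_INTEGRAL:
            raise ValueError("inputs must be line-integral sinograms")
        if np.any(sino.data < 0):
            raise ValueError("negative optical depth in projection data")
        term = w * np.exp(-sino.data)
        lam = term if lam is None else lam + term
    lam = spectrum.i0 * lam
    expected = Sinogram(data=lam, angles_deg=proto.angles_deg,
                        detector_spacing=proto.detector_spacing,
                        kind=PHOTON_COUNT, meta=dict(proto.meta))
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam).astype(np.float64)
    else:
        counts = lam.copy()
    realized = Sinogram(data=counts, angles_deg=proto.angles_deg,
                        detector_spacing=proto.detector_spacing,
                        kind=PHOTON_COUNT,
                        meta=dict(proto.meta, seed=seed, noise=noise))
    return realized, expected


def counts_to_line_integrals(counts: Sinogram, spectrum: Spectrum,
                             floor: float = 1.0) -> Sinogram:
    """Log conversion with a photon-starvation floor.

    ``p = -ln(max(counts, floor) / i0)``.  Rays extinguished by thick metal
    are clipped at the floor (default one count); that clipping is the
    dominant source of streak artifacts.
    """
    if np.any(counts.data < 0):
        raise ValueError("photon counts must be non-negative")
    p = -np.log(np.maximum(counts.data, floor) / spectrum.i0)
    return Sinogram(data=p, angles_deg=counts.angles_deg,
                    detector_spacing=counts.detector_spacing,
                    kind=LINE_INTEGRAL, meta=dict(counts.meta))


@dataclass
class SimConfig:
    """Artifact-simulation configuration (geometry, spectrum, noise).

    Defaults: 720 parallel-beam views over [0, 180) degrees, detector pitch
    equal to the pixel pitch, a filtered 120 kVp spectrum with 2e5 incident
    photons per detector element, Poisson noise on, and HU recalibration at
    an effective energy of 70 keV after reconstruction.
    """

    n_views: int = 720
    spectrum: Spectrum = field(default_factory=filtered_kramers_spectrum)
    noise: bool = True
    lung_max: float = -300.0
    bone_min: float = 150.0
    metal_min: float = 2000.0
    e_eff_keV: float | None = None  # None -> water-calibrated from spectrum
    count_floor: float = 1.0
    density_model: str = "consistent"
    table: AttenuationTable = field(default_factory=AttenuationTable.default)

    @property
    def recal_energy_keV(self) -> float:
        """HU recalibration energy: explicit, or water-calibrated."""
        if self.e_eff_keV is not None:
            return self.e_eff_keV
        return effective_energy(self.spectrum, self.table)


def _class_density_sinograms(ct: CTSlice, masks: TissueMaskSet,
                             cfg: SimConfig) -> dict:
    angles = default_angles(cfg.n_views)
    rho = density_map(ct, masks, cfg.table, cfg.density_model,
                      cfg.recal_energy_keV)
    sinos = {}
    for name in MASK_MATERIAL:
        m = getattr(masks, name)
        if np.any(m):
            sinos[name] = forward_project(np.where(m, rho, 0.0),
                                          ct.pixel_spacing, angles)
    return sinos, angles


def simulate_artifact(ct_ref: CTSlice, metal_mask: np.ndarray | None,
                      cfg: SimConfig | None = None,
                      seed: int | None = None) -> CTSlice:
    """Full simulation chain producing the artifacted slice CT_art.

    ``ct_ref`` is the slice to push through the scanner model (it may
    already contain the transducer overlay); ``metal_mask`` marks the pixels
    treated as piezoceramic metal regardless of threshold segmentation
    (pass ``None`` to rely on the HU threshold alone).
    """
    cfg = cfg or SimConfig()
    masks = segment_tissues(ct_ref, cfg.lung_max, cfg.bone_min, cfg.metal_min)
    if metal_mask is not None:
        metal = masks.metal | metal_mask.astype(bool)
        masks = TissueMaskSet(
            lung=masks.lung & ~metal,
            water_equiv=masks.water_equiv & ~metal,
            bone=masks.bone & ~metal,
            metal=metal & ~masks.background,
            background=masks.background)

    class_sinos, angles = _class_density_sinograms(ct_ref, masks, cfg)
    proto = next(iter(class_sinos.values()))

    per_energy = []
    for e in cfg.spectrum.energies_keV:
        data = np.zeros_like(proto.data)
        for name, sino in class_sinos.items():
            data += sino.data * float(
                cfg.table.mu_over_rho(MASK_MATERIAL[name], e))
        per_energy.append(Sinogram(data=data, angles_deg=angles,
                                   detector_spacing=proto.detector_spacing,
                                   kind=LINE_INTEGRAL))

    realized, _ = polychromatic_counts(per_energy, cfg.spectrum, seed=seed,
                                       noise=cfg.noise)
    p = counts_to_line_integrals(realized, cfg.spectrum, floor=cfg.count_floor)
    mu_rec = reconstruct_fbp(p, ct_ref.shape[0], ct_ref.pixel_spacing)
    e_eff = cfg.recal_energy_keV
    hu = mu_to_hu(mu_rec, cfg.table, e_eff)
    return CTSlice(values=hu, pixel_spacing=ct_ref.pixel_spacing,
                   thickness=ct_ref.thickness, id=ct_ref.id + "-art",
                   meta={"seed": seed, "noise": cfg.noise,
                         "n_views": cfg.n_views,
                         "spectrum_kev": cfg.spectrum.energies_keV.tolist(),
                         "i0": cfg.spectrum.i0, "e_eff_keV": e_eff,
                         "source": ct_ref.id})


def starvation_path_cm(spectrum: Spectrum,
                       table: AttenuationTable | None = None,
                       floor: float = 1.0) -> float:
    """Metal path length at which a ray's expected counts hit the floor.

    Solves ``i0 * sum_E w_E exp(-mu_pzt(E) L) = floor`` for ``L`` by
    bisection.  Rays traversing more piezoceramic than this are photon
    starved, i.e. actually corrupted by the count clipping.
    """
    table = table or DEFAULT_TABLE
    mu = table.mu("pzt_metal", spectrum.energies_keV)
    target = floor / spectrum.i0

    def trans(L):
        return float(np.sum(spectrum.weights * np.exp(-mu * L)))

    lo, hi = 0.0, 100.0
    if trans(hi) > target:
        return np.inf
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if trans(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def metal_crossing_mask(metal_mask: np.ndarray, pixel_spacing: float,
                        angles_deg: np.ndarray,
                        min_path_cm: float = 0.0) -> np.ndarray:
    """Pixels lying on a ray that traverses metal (optionally: enough metal).

    With ``min_path_cm = 0`` the union over a 180-degree view set is the
    whole image (every pixel lies on some line through the metal), so for
    artifact-locality analysis pass the photon-starvation length from
    :func:`starvation_path_cm` — the region then covers exactly the rays
    whose projections are corrupted by count clipping and that carry the
    streaks.
    """
    shadow = forward_project(metal_mask.astype(np.float64), pixel_spacing,
                             angles_deg)
    n = metal_mask.shape[0]
    h = pixel_spacing / 10.0
    c = (np.arange(n) - (n - 1) / 2.0) * h
    X, Y = np.meshgrid(c, c)
    nd = shadow.n_detectors
    d_cm = shadow.detector_spacing / 10.0
    center = (nd - 1) / 2.0
    hit = np.zeros((n, n), dtype=bool)
    crossing = shadow.data > max(min_path_cm, 1e-9)
    for k, a in enumerate(angles_deg):
        th = np.deg2rad(a)
        fi = np.rint((X * np.cos(th) + Y * np.sin(th)) / d_cm
                     + center).astype(np.int64)
        ok = (fi >= 0) & (fi < nd)
        fi = np.clip(fi, 0, nd - 1)
        hit |= ok & crossing[k][fi]
    return hit


def streak_index(ct_art: CTSlice, ct_ref: CTSlice,
                 crossing: np.ndarray, body: np.ndarray) -> float:
    """Std of the HU error on metal-crossing rays minus off them (body only).

    Positive values mean artifact energy is concentrated along rays through
    metal — the streak morphology.
    """
    diff = ct_art.values - ct_ref.values
    on = diff[crossing & body]
    off = diff[~crossing & body]
    if on.size == 0 or off.size == 0:
        raise ValueError("crossing mask must split the body into two parts")
    return float(on.std() - off.std())
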