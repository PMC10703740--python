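"""Data plumbing for network training: normalization, paired augmentation,
and leakage-free patient-level splits.

HU values are clipped to [-1000, 1000] and scaled to [-1, 1]; out-of-field
pixels created by geometric augmentation are filled with -1 (air).  Every
augmentation draws ONE transform and applies it to both members of a pair,
so the (ref, art) alignment survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import transform as sktf

from ..core import CTSlice

__all__ = [
    "HU_CLIP",
    "normalize",
    "denormalize",
    "AugmentToggles",
    "augment_pair",
    "kfold_split",
    "holdout_split",
]

HU_CLIP = 1000.0


def normalize(ct: CTSlice | np.ndarray) -> np.ndarray:
    """Clip HU to [-1000, 1000] and scale to [-1, 1] (float32)."""
    v = ct.values if isinstance(ct, CTSlice) else np.asarray(ct)
    if not np.all(np.isfinite(v)):
        raise ValueError("cannot normalize non-finite HU values")
    return (np.clip(v, -HU_CLIP, HU_CLIP) / HU_CLIP).astype(np.float32)


def denormalize(arr: np.ndarray, like: CTSlice | None = None) -> CTSlice:
    """Inverse scaling back to HU; metadata copied from ``like`` if given."""
    hu = np.asarray(arr, dtype=np.float64) * HU_CLIP
    if like is not None:
        out = like.copy(values=hu)
        return out
    return CTSlice(values=hu)


@dataclass
class AugmentToggles:
    """Which of the four training augmentations are active."""

    rotation: bool = True
    horizontal_flip: bool = True
    resized_crop: bool = True
    perspective: bool = True

    def any(self) -> bool:
        return (self.rotation or self.horizontal_flip or self.resized_crop
                or self.perspective)


def _warp(img: np.ndarray, tform, order: int = 1) -> np.ndarray:
    return sktf.warp(img.astype(np.float64), tform, order=order, cval=-1.0,
                     mode="constant", preserve_range=True
                     ).astype(np.float32)


def augment_pair(ref: np.ndarray, art: np.ndarray,
                 toggles: AugmentToggles | None = None,
                 rng: np.random.Generator | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Jointly augment a normalized (ref, art) pair.

    Ranges: rotation +/-10 degrees, crop scale 0.8-1.0 (resized back), mild
    corner-jitter perspective, 50% horizontal flip.  The same sampled
    transform hits both images; all randomness comes from ``rng``.
    """
    toggles = toggles or AugmentToggles()
    rng = rng or np.random.default_rng(0)
    if not toggles.any():
        return ref, art
    ref = np.asarray(ref, dtype=np.float32)
    art = np.asarray(art, dtype=np.float32)
    n = ref.shape[0]

    if toggles.horizontal_flip and rng.random() < 0.5:
        ref, art = ref[:, ::-1].copy(), art[:, ::-1].copy()

    if toggles.rotation:
        ang = rng.uniform(-10.0, 10.0)
        ref = ndimage.rotate(ref, ang, reshape=False, order=1, cval=-1.0)
        art = ndimage.rotate(art, ang, reshape=False, order=1, cval=-1.0)

    if toggles.resized_crop:
        scale = rng.uniform(0.8, 1.0)
        side = max(4, int(round(scale * n)))
        r0 = rng.integers(0, n - side + 1)
        c0 = rng.integers(0, n - side + 1)
        ref = sktf.resize(ref[r0:r0 + side, c0:c0 + side], (n, n), order=1,
                          preserve_range=True, anti_aliasing=False
                          ).astype(np.float32)
        art = sktf.resize(art[r0:r0 + side, c0:c0 + side], (n, n), order=1,
                          preserve_range=True, anti_aliasing=False
                          ).astype(np.float32)

    if toggles.perspective:
        jit = 0.04 * n
        src = np.array([[0, 0], [0, n], [n, n], [n, 0]], dtype=np.float64)
        dst = src + rng.uniform(-jit, jit, size=(4, 2))
        if hasattr(sktf.ProjectiveTransform, "from_estimate"):
            tform = sktf.ProjectiveTransform.from_estimate(dst, src)
        else:  # older scikit-image
            tform = sktf.ProjectiveTransform()
            tform.estimate(dst, src)
        ref = _warp(ref, tform)
        art = _warp(art, tform)

    return np.clip(ref, -1.0, 1.0), np.clip(art, -1.0, 1.0)


def _patient_ids(samples) -> list[str]:
    ids = []
    for s in samples:
        pid = s.patient_id if hasattr(s, "patient_id") else str(s)
        if pid not in ids:
            ids.append(pid)
    return ids


def kfold_split(samples, folds: int = 5, seed: int = 0) -> dict[str, int]:
    """Patient-level k-fold assignment (no patient spans two folds).

    Returns patient-id -> fold index in [0, folds).  Slices are never split
    individually, so nothing leaks across folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    patients = _patient_ids(samples)
    if len(patients) < folds:
        raise ValueError(
            f"{len(patients)} patients cannot fill {folds} folds")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    return {pid: i % folds for i, pid in enumerate(order)}


def holdout_split(samples, test_fraction: float = 0.15, seed: int = 0
                  ) -> tuple[list, list]:
    """Patient-level train/test holdout (default 85/15).

    Returns (train_samples, test_samples); every patient lands wholly on
    one side.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    patients = _patient_ids(samples)
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    n_test = max(1, int(round(test_fraction * len(patients))))
    test_ids = set(order[:n_test])
    train = [s for s in samples if s.patient_id not in test_ids]
    test = [s for s in samples if s.patient_id in test_ids]
    return train, test
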