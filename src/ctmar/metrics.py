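"""Evaluation surface: image-quality metrics and HU restoration.

SSIM, PSNR and RMSE are computed against the artifact-free reference slice;
region statistics (heart, lungs, bone) report contour-based mean/STD HU and
their deviations, and the mean-HU-improvement percentage quantifies how much
of the artifact-induced deviation a correction removed:

    improvement % = 100 * (|dmean_art| - |dmean_cor|) / |dmean_art|

where |dmean_*| is the absolute difference of the region mean HU versus the
reference.  Because the improvement can be aggregated either from overall
mean deltas or as the mean of per-scan percentages — and the two differ —
:func:`build_report` reports both, labelled.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.metrics import structural_similarity

from .core import CTSlice

__all__ = [
    "rmse", "psnr", "ssim", "region_hu_stats", "hu_improvement_percent",
    "RegionHuStats", "MetricsReport", "build_report", "write_report",
]

DATA_RANGE_HU = 2000.0  # the clipped span [-1000, 1000]


def _values(a) -> np.ndarray:
    return a.values if isinstance(a, CTSlice) else np.asarray(a, float)


def rmse(a, b, mask: np.ndarray | None = None) -> float:
    """Root-mean-square error in HU, optionally restricted to a mask."""
    av, bv = _values(a), _values(b)
    if av.shape != bv.shape:
        raise ValueError("slices must be congruent")
    d = av - bv
    if mask is not None:
        if not np.any(mask):
            raise ValueError("empty mask")
        d = d[mask]
    return float(np.sqrt(np.mean(d * d)))


def psnr(a, b, data_range: float = DATA_RANGE_HU) -> float:
    """Peak signal-to-noise ratio, dB: 20 log10(range / rmse).

    Identical inputs return ``inf`` (sentinel for a zero-error pair).
    """
    r = rmse(a, b)
    if r == 0.0:
        return math.inf
    return float(20.0 * np.log10(data_range / r))


def ssim(a, b, data_range: float = DATA_RANGE_HU) -> float:
    """Mean structural similarity (11x11 Gaussian window, sigma 1.5).

    The canonical formulation: Gaussian-weighted local statistics,
    stabilizers k1=0.01, k2=0.03 on the given dynamic range, population
    covariance.
    """
    av, bv = _values(a), _values(b)
    if av.shape != bv.shape:
        raise ValueError("slices must be congruent")
    if min(av.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    return float(structural_similarity(
        av, bv, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


@dataclass
class RegionHuStats:
    """Contour-based HU statistics for one region of one slice."""

    region: str
    mean_hu: float
    std_hu: float
    pixel_count: int
    abs_dmean_hu: Optional[float] = None  # |mean - mean_ref|
    dstd_hu: Optional[float] = None       # std - std_ref


def region_hu_stats(ct, region_mask: np.ndarray, region: str = "",
                    reference=None) -> RegionHuStats:
    """Mean and population STD of HU over a contour mask.

    With a reference slice, also reports |dmean| and the STD difference
    versus it.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not np.any(region_mask):
        raise ValueError(f"empty region mask {region!r}")
    v = _values(ct)[region_mask]
    stats = RegionHuStats(region=region, mean_hu=float(v.mean()),
                          std_hu=float(v.std()), pixel_count=int(v.size))
    if reference is not None:
        rv = _values(reference)[region_mask]
        stats.abs_dmean_hu = float(abs(v.mean() - rv.mean()))
        stats.dstd_hu = float(v.std() - rv.std())
    return stats


def hu_improvement_percent(delta_art: float, delta_cor: float) -> float:
    """Mean-HU-value improvement percentage.

    Both arguments are absolute mean-HU deviations versus the reference
    (sign convention enforced here); a perfect restoration gives 100, no
    change 0, a worsened deviation is negative.  ``delta_art = 0`` has no
    defined improvement and returns NaN.
    """
    delta_art, delta_cor = abs(delta_art), abs(delta_cor)
    if delta_art == 0.0:
        return math.nan
    return float(100.0 * (delta_art - delta_cor) / delta_art)


@dataclass
class MetricsReport:
    """Per-slice rows plus aggregate (mean, STD) tables per algorithm."""

    rows: list = field(default_factory=list)        # per-slice dicts
    aggregates: dict = field(default_factory=dict)  # algorithm -> metric -> (mean, std)
    region_tables: dict = field(default_factory=dict)
    improvements: dict = field(default_factory=dict)


def _agg(vals: list[float]) -> tuple[float, float]:
    a = np.asarray(vals, dtype=float)
    return float(a.mean()), float(a.std())


def build_report(samples: list, region_masks: dict | None = None,
                 algorithms: tuple = ("art", "cor")) -> MetricsReport:
    """Aggregate image-quality and HU-restoration metrics over paired samples.

    ``samples`` are :class:`~ctmar.core.PairedSample` objects whose ``cor``
    field may be None (then only the artifacted column is reported);
    ``region_masks`` maps sample.slice_id -> {region: mask} for the
    contour-based HU tables.  Improvement percentages are computed both from
    the overall mean deltas ("aggregate" mode) and as the mean of per-scan
    percentages ("per_scan" mode).
    """
    rep = MetricsReport()
    per_alg: dict[str, dict[str, list]] = {}
    region_acc: dict[tuple, dict[str, list]] = {}

    # canonical order: aggregates are exactly invariant to input permutation
    samples = sorted(samples, key=lambda s: (s.patient_id, s.slice_id))
    for s in samples:
        images = {"art": s.art}
        if "cor" in algorithms:
            if s.cor is None:
                raise ValueError(f"sample {s.slice_id!r} has no corrected "
                                 "slice but 'cor' was requested")
            images["cor"] = s.cor
        for alg, img in images.items():
            row = {"patient": s.patient_id, "slice": s.slice_id,
                   "algorithm": alg,
                   "ssim": ssim(img, s.ref), "psnr": psnr(img, s.ref),
                   "rmse": rmse(img, s.ref)}
            rep.rows.append(row)
            d = per_alg.setdefault(alg, {"ssim": [], "psnr": [], "rmse": []})
            for m in ("ssim", "psnr", "rmse"):
                d[m].append(row[m])
            if region_masks and s.slice_id in region_masks:
                for region, mask in region_masks[s.slice_id].items():
                    st = region_hu_stats(img, mask, region, reference=s.ref)
                    acc = region_acc.setdefault((alg, region), {
                        "mean": [], "std": [], "dmean": [], "dstd": []})
                    acc["mean"].append(st.mean_hu)
                    acc["std"].append(st.std_hu)
                    acc["dmean"].append(st.abs_dmean_hu)
                    acc["dstd"].append(st.dstd_hu)

    for alg, metrics in per_alg.items():
        rep.aggregates[alg] = {m: _agg(v) for m, v in metrics.items()}
    for (alg, region), acc in region_acc.items():
        rep.region_tables.setdefault(alg, {})[region] = {
            k: _agg(v) for k, v in acc.items()}

    if region_masks and "cor" in per_alg:
        for region in {r for (_, r) in region_acc}:
            art = region_acc.get(("art", region))
            cor = region_acc.get(("cor", region))
            if not art or not cor:
                continue
            agg = hu_improvement_percent(np.mean(art["dmean"]),
                                         np.mean(cor["dmean"]))
            per_scan = float(np.mean([
                hu_improvement_percent(a, c)
                for a, c in zip(art["dmean"], cor["dmean"]) if a > 0]))
            rep.improvements[region] = {"aggregate": agg,
                                        "per_scan": per_scan}
    return rep


def write_report(rep: MetricsReport, out_dir) -> None:
    """Write the per-slice table (TSV) and aggregate summaries."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "per_slice.tsv", "w", newline="") as fh:
        cols = ["patient", "slice", "algorithm", "ssim", "psnr", "rmse"]
        w = csv.DictWriter(fh, fieldnames=cols, delimiter="\t")
        w.writeheader()
        for row in sorted(rep.rows, key=lambda r: (r["patient"], r["slice"],
                                                   r["algorithm"])):
            w.writerow({k: (f"{v:.6g}" if isinstance(v, float) else v)
                        for k, v in row.items()})
    summary = {"aggregates": rep.aggregates,
               "region_tables": rep.region_tables,
               "improvements": rep.improvements}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
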