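"""Quantitative evaluation of reconstructed contrasts and parameter maps.

NRMSE scores the parameter maps over an evaluation region Phi built from the
requested region variant (whole image, T2 <= 120 ms, T1 <= 1000 ms, or an
external tissue mask) intersected with outlier-exclusion rules: predicted
T1 above 5000 ms or predicted T2 above 500 ms are excluded, as are pixels
whose ground-truth first-contrast magnitude falls below 5% of its maximum,
and pixels invalid in either fit. SSIM scores the magnitude contrast images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from skimage.metrics import structural_similarity

from .signal_models import ParameterMaps

REGION_MODES = ("whole", "t2_le_120", "t1_le_1000", "external_mask")

T1_EXCLUDE_MS = 5000.0
T2_EXCLUDE_MS = 500.0
INTENSITY_FRACTION = 0.05
T2_REGION_MS = 120.0
T1_REGION_MS = 1000.0


@dataclass
class RegionSpec:
    """Which image region a metric is computed over."""

    mode: str = "whole"
    external: Optional[np.ndarray] = None
    strict: bool = False  # use < instead of <= for the region thresholds

    def __post_init__(self):
        if self.mode not in REGION_MODES:
            raise ValueError(f"unknown region mode {self.mode!r}")
        if (self.mode == "external_mask") != (self.external is not None):
            raise ValueError("external mask required iff mode is 'external_mask'")
        if self.external is not None:
            self.external = np.asarray(self.external, dtype=bool)

    def base_mask(self, gt_maps: ParameterMaps) -> np.ndarray:
        shape = gt_maps.t2.shape
        if self.mode == "whole":
            return np.ones(shape, dtype=bool)
        if self.mode == "t2_le_120":
            return (gt_maps.t2 < T2_REGION_MS) if self.strict else (gt_maps.t2 <= T2_REGION_MS)
        if self.mode == "t1_le_1000":
            return (gt_maps.t1 < T1_REGION_MS) if self.strict else (gt_maps.t1 <= T1_REGION_MS)
        if self.external.shape != shape:
            raise ValueError("external mask shape does not match the maps")
        return self.external


def evaluation_region(gt_maps: ParameterMaps, pred_maps: ParameterMaps,
                      gt_contrasts: np.ndarray, region: RegionSpec,
                      evaluate_t1: bool = True, evaluate_t2: bool = True) -> np.ndarray:
    """Evaluation region Phi: region variant plus outlier-exclusion rules."""
    phi = region.base_mask(gt_maps)
    if phi.shape != pred_maps.t2.shape:
        raise ValueError("region mask shape does not match the maps")
    if evaluate_t1:
        phi = phi & (pred_maps.t1 <= T1_EXCLUDE_MS)
    if evaluate_t2:
        phi = phi & (pred_maps.t2 <= T2_EXCLUDE_MS)
    mag0 = np.abs(np.asarray(gt_contrasts)[0])
    if mag0.shape != phi.shape:
        raise ValueError("contrast image shape does not match the maps")
    phi = phi & (mag0 >= INTENSITY_FRACTION * mag0.max())
    phi = phi & gt_maps.validity & pred_maps.validity
    return phi


def nrmse(pred: np.ndarray, gt: np.ndarray, phi: np.ndarray,
          normalization: str = "euclidean") -> float:
    """Normalized RMS error of ``pred`` against ``gt`` over region ``phi``.

    Default normalization divides by the Euclidean norm of the ground truth
    over ``phi``; 'mean' and 'range' variants divide the plain RMSE by the GT
    mean or range instead.
    """
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    phi = np.asarray(phi, dtype=bool)
    if pred.shape != gt.shape or phi.shape != gt.shape:
        raise ValueError("pred, gt and phi must share a shape")
    if not phi.any():
        raise ValueError("evaluation region is empty")
    d = pred[phi] - gt[phi]
    g = gt[phi]
    if normalization == "euclidean":
        denom = np.linalg.norm(g)
        if denom == 0:
            raise ValueError("ground truth is zero over the evaluation region")
        return float(np.linalg.norm(d) / denom)
    rmse = float(np.sqrt(np.mean(d ** 2)))
    if normalization == "mean":
        denom = float(np.abs(g.mean()))
    elif normalization == "range":
        denom = float(g.max() - g.min())
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if denom == 0:
        raise ValueError("degenerate normalization over the evaluation region")
    return rmse / denom


def ssim(pred: np.ndarray, ref: np.ndarray) -> float:
    """Mean single-scale SSIM with an 11x11 Gaussian window (sigma 1.5).

    Constants K1=0.01, K2=0.03; data range is the reference maximum
    (magnitude images are non-negative).
    """
    pred = np.abs(np.asarray(pred, dtype=np.float64))
    ref = np.abs(np.asarray(ref, dtype=np.float64))
    if pred.shape != ref.shape:
        raise ValueError("images must share a shape")
    return float(structural_similarity(
        ref, pred, win_size=11, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03,
        data_range=float(ref.max())))


@dataclass
class MetricsReport:
    """Per-case SSIM/NRMSE plus across-case aggregates."""

    ssim_per_contrast: List[List[float]] = field(default_factory=list)  # case x contrast
    nrmse_per_region: List[Dict[str, Dict[str, float]]] = field(default_factory=list)

    def validate(self):
        for row in self.ssim_per_contrast:
            if any(v > 1.0 + 1e-12 for v in row):
                raise ValueError("SSIM cannot exceed 1")
        for case in self.nrmse_per_region:
            for region in case.values():
                if any(v < 0 for v in region.values()):
                    raise ValueError("NRMSE cannot be negative")

    def aggregate(self) -> Dict[str, Dict[str, float]]:
        """Mean and SD across cases for every metric."""
        out: Dict[str, Dict[str, float]] = {}
        if self.ssim_per_contrast:
            arr = np.asarray(self.ssim_per_contrast, dtype=np.float64)
            for p in range(arr.shape[1]):
                out[f"ssim_contrast{p}"] = {"mean": float(arr[:, p].mean()),
                                            "sd": float(arr[:, p].std(ddof=0))}
        keys = {}
        for case in self.nrmse_per_region:
            for rname, maps in case.items():
                for mname, v in maps.items():
                    keys.setdefault((rname, mname), []).append(v)
        for (rname, mname), vals in keys.items():
            a = np.asarray(vals, dtype=np.float64)
            out[f"nrmse_{rname}_{mname}"] = {"mean": float(a.mean()),
                                             "sd": float(a.std(ddof=0))}
        return out


def evaluate_case(recon_contrasts: np.ndarray, gt_contrasts: np.ndarray,
                  pred_maps: ParameterMaps, gt_maps: ParameterMaps,
                  regions: Sequence[RegionSpec], maps=("t2",),
                  report: Optional[MetricsReport] = None) -> MetricsReport:
    """Score one case and append it to (or create) a :class:`MetricsReport`."""
    recon_contrasts = np.asarray(recon_contrasts)
    gt_contrasts = np.asarray(gt_contrasts)
    if recon_contrasts.shape != gt_contrasts.shape:
        raise ValueError("contrast stacks must share a shape")
    report = report if report is not None else MetricsReport()
    report.ssim_per_contrast.append(
        [ssim(recon_contrasts[p], gt_contrasts[p]) for p in range(gt_contrasts.shape[0])])
    row: Dict[str, Dict[str, float]] = {}
    for region in regions:
        phi = evaluation_region(gt_maps, pred_maps, gt_contrasts, region,
                                evaluate_t1="t1" in maps, evaluate_t2="t2" in maps)
        row[region.mode] = {
            m: nrmse(getattr(pred_maps, m), getattr(gt_maps, m), phi) for m in maps
        }
    report.nrmse_per_region.append(row)
    report.validate()
    return report
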