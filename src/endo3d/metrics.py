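"""Quantitative image and disparity evaluation.

PSNR is ``10 log10(MAX^2 / MSE)`` with the MSE taken over all pixels and
channels; identical images report ``inf``.  SSIM shares the loss module's
windowed implementation so the training objective and the reported metric
agree.  Disparity accuracy is mean absolute / root-mean-square error in
pixels (an optional mm-per-pixel factor converts to millimetres when a
calibration is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import imgio
from .losses import ssim_map


@dataclass
class MetricsReport:
    psnr: list[float] = field(default_factory=list)
    ssim: list[float] = field(default_factory=list)
    mae: list[float] = field(default_factory=list)
    rmse: list[float] = field(default_factory=list)
    max_value: float = 1.0

    @property
    def n_images(self) -> int:
        return max(len(self.psnr), len(self.ssim), len(self.mae))

    def summary(self) -> dict:
        def stats(vals):
            if not vals:
                return None
            arr = np.asarray(vals, dtype=np.float64)
            finite = arr[np.isfinite(arr)]
            return {
                "mean": float(finite.mean()) if finite.size else float("inf"),
                "std": float(finite.std()) if finite.size else 0.0,
                "per_image": [float(v) for v in arr],
            }

        return {
            "n_images": self.n_images,
            "max_value": self.max_value,
            "psnr_db": stats(self.psnr),
            "ssim": stats(self.ssim),
            "mae": stats(self.mae),
            "rmse": stats(self.rmse),
        }

    def write(self, path) -> None:
        imgio.write_json(path, self.summary())


def psnr(reference: np.ndarray, test: np.ndarray, max_value: float = 1.0) -> float:
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_value ** 2 / mse)


def ssim_index(x: np.ndarray, y: np.ndarray, window: int = 3,
               data_range: float = 1.0) -> float:
    return float(np.mean(ssim_map(x, y, window=window, data_range=data_range)))


def disparity_errors(pred: np.ndarray, truth: np.ndarray,
                     valid_mask: np.ndarray | None = None,
                     mm_per_pixel: float | None = None) -> tuple[float, float]:
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if valid_mask is None:
        valid_mask = np.ones(pred.shape, dtype=bool)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if not valid_mask.any():
        raise ValueError("valid mask is empty")
    err = pred[valid_mask] - truth[valid_mask]
    scale = mm_per_pixel if mm_per_pixel is not None else 1.0
    mae = float(np.mean(np.abs(err))) * scale
    rmse = float(np.sqrt(np.mean(err ** 2))) * scale
    return mae, rmse


def evaluate_batch(pred_images, ref_images, pred_disp=None, truth_disp=None,
                   max_value: float = 1.0, out_path=None) -> MetricsReport:
    """Aggregate PSNR/SSIM over image pairs (and MAE/RMSE over disparity
    pairs when given); optionally writes the JSON report."""
    pred_images, ref_images = list(pred_images), list(ref_images)
    if not pred_images or len(pred_images) != len(ref_images):
        raise ValueError("need equally many (nonzero) predicted and reference images")
    report = MetricsReport(max_value=max_value)
    for p, r in zip(pred_images, ref_images):
        report.psnr.append(psnr(r, p, max_value))
        report.ssim.append(ssim_index(r, p, data_range=max_value))
    if pred_disp is not None and truth_disp is not None:
        for dp, dt in zip(pred_disp, truth_disp):
            mae, rmse = disparity_errors(dp, dt)
            report.mae.append(mae)
            report.rmse.append(rmse)
    if out_path is not None:
        report.write(out_path)
    return report
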