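"""Signal-quality and multi-label classification metrics.

SNR follows the power-ratio definition 10*log10(sum X^2 / sum (X-Y)^2) with X
the clean reference; it is negative when the error power exceeds the signal
power.  Multi-lead records are scored per lead and averaged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from .ecgsynth import EcgRecord

logger = logging.getLogger(__name__)


def _paired(clean, test) -> tuple[np.ndarray, np.ndarray]:
    x = np.atleast_2d(np.asarray(clean, dtype=float))
    y = np.atleast_2d(np.asarray(test, dtype=float))
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def snr(clean, test) -> float:
    """Signal-to-noise ratio in dB of `test` against the clean reference.

    Identical inputs have no residual; that degenerate case is reported as the
    +inf sentinel rather than raising.
    """
    x, y = _paired(clean, test)
    p_sig = (x**2).sum(axis=1)
    p_err = ((x - y) ** 2).sum(axis=1)
    with np.errstate(divide="ignore"):
        per_lead = 10.0 * np.log10(np.where(p_err > 0, p_sig / np.where(p_err > 0, p_err, 1.0), np.inf))
    return float(per_lead.mean())


def mse(clean, test) -> float:
    """Mean squared residual between the clean reference and `test`."""
    x, y = _paired(clean, test)
    return float(((x - y) ** 2).mean())


def multilabel_report(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Micro/macro precision, recall, F1 plus subset accuracy.

    Classes with no predicted (or no true) positives contribute 0 to the
    macro averages; a warning is logged when that happens.
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.ndim == 1:
        pred, truth = pred[None, :], truth[None, :]
    empty_pred = (pred.sum(axis=0) == 0) & (truth.sum(axis=0) > 0)
    empty_true = truth.sum(axis=0) == 0
    if empty_pred.any() or empty_true.any():
        logger.warning(
            "zero-division in per-class metrics: %d classes without predictions, "
            "%d without true positives; they contribute 0",
            int(empty_pred.sum()),
            int(empty_true.sum()),
        )
    out: dict[str, float] = {}
    for average in ("micro", "macro"):
        p, r, f1, _ = precision_recall_fscore_support(
            truth, pred, average=average, zero_division=0
        )
        out[f"precision_{average}"] = float(p)
        out[f"recall_{average}"] = float(r)
        out[f"f1_{average}"] = float(f1)
    out["subset_accuracy"] = float((pred == truth).all(axis=1).mean())
    return out


@dataclass
class DenoiseReport:
    """Per-record before/after signal quality, with aggregates."""

    snr_before_db: list[float] = field(default_factory=list)
    snr_after_db: list[float] = field(default_factory=list)
    mse_before: list[float] = field(default_factory=list)
    mse_after: list[float] = field(default_factory=list)

    @property
    def mean_snr_before_db(self) -> float:
        return float(np.mean(self.snr_before_db))

    @property
    def mean_snr_after_db(self) -> float:
        return float(np.mean(self.snr_after_db))

    @property
    def mean_snr_improvement_db(self) -> float:
        return self.mean_snr_after_db - self.mean_snr_before_db

    @property
    def mean_mse_before(self) -> float:
        return float(np.mean(self.mse_before))

    @property
    def mean_mse_after(self) -> float:
        return float(np.mean(self.mse_after))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snr_before_db": self.snr_before_db,
                "snr_after_db": self.snr_after_db,
                "mse_before": self.mse_before,
                "mse_after": self.mse_after,
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        """Method x {SNR, MSE} table mirroring a before/after comparison."""
        return pd.DataFrame(
            {
                "SNR": [self.mean_snr_before_db, self.mean_snr_after_db],
                "MSE": [self.mean_mse_before, self.mean_mse_after],
            },
            index=["before", "after"],
        )


def evaluate_denoiser(model, pairs) -> DenoiseReport:
    """Before/after metrics of a denoiser over (clean, noisy) record pairs.

    `model` is anything with a ``denoise_record(record) -> record`` method, or
    a bare callable on records.
    """
    fn = model.denoise_record if hasattr(model, "denoise_record") else model
    report = DenoiseReport()
    for clean, noisy in pairs:
        denoised = fn(noisy)
        report.snr_before_db.append(snr(clean.signal, noisy.signal))
        report.snr_after_db.append(snr(clean.signal, denoised.signal))
        report.mse_before.append(mse(clean.signal, noisy.signal))
        report.mse_after.append(mse(clean.signal, denoised.signal))
    return report


def moving_average_record(record: EcgRecord, width: int = 9) -> EcgRecord:
    """Trivial moving-average reference filter (smoke-test baseline only)."""
    kernel = np.ones(width) / width
    smoothed = np.vstack(
        [np.convolve(lead, kernel, mode="same") for lead in record.signal]
    )
    return record.copy(signal=smoothed, filtered="moving_average")
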