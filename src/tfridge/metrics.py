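"""Evaluation metrics for estimated ridge maps.

The central indicator compares local component counts between the
reference TFD (the full-autoterm LO-ADTFD) and the binary estimate,
slice by slice, normalized by the larger of the two counts so signals
of different component density are comparable:

    err(s) = |NC_ref(s) - NC_est(s)| / max(NC_ref(s), NC_est(s))

averaged as squared (MSE) or absolute (MAE) error per axis and then
across the two axes.  A 0/0 slice contributes 0 (both representations
agree there is no component there).

F1 with precision/recall scores estimated ridge pixels against the
ideal ridge sample set of the synthetic truth; the F-norm is the scaled
squared Frobenius distance between two binary maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import (
    InvalidInputError,
    LocalCountProfile,
    RidgeMap,
    TFDGrid,
)
from .renyi import LocalizationParams

__all__ = [
    "MetricsReport",
    "normalized_count_error",
    "lre_error",
    "f1_score",
    "fnorm",
    "count_profile_mse",
]


@dataclass
class MetricsReport:
    """All quality numbers for one estimation run."""

    mse_t: float
    mse_f: float
    mse_tf: float
    mae_t: float
    mae_f: float
    mae_tf: float
    f1: float = 0.0
    precision: float = 0.0
    recall: float = 0.0
    fnorm: float = 0.0
    nr: int = 0

    def __post_init__(self):
        if abs(self.mse_tf - (self.mse_t + self.mse_f) / 2) > 1e-9:
            raise InvalidInputError("mse_tf must be the mean of mse_t and mse_f")
        if abs(self.mae_tf - (self.mae_t + self.mae_f) / 2) > 1e-9:
            raise InvalidInputError("mae_tf must be the mean of mae_t and mae_f")
        if self.precision + self.recall > 0:
            f1 = 2 * self.precision * self.recall / (self.precision + self.recall)
        else:
            f1 = 0.0
        if abs(self.f1 - f1) > 1e-12:
            raise InvalidInputError("f1 inconsistent with precision and recall")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("mse_t", "mse_f", "mse_tf", "mae_t", "mae_f", "mae_tf",
                 "f1", "precision", "recall", "fnorm", "nr")}


def normalized_count_error(ref: np.ndarray, est: np.ndarray) -> np.ndarray:
    """|a - b| / max(a, b) per slice, with 0/0 slices contributing 0.

    The counts are real-valued estimates of integer component numbers,
    so "no component on either side" is judged on the rounded counts: a
    slice where both profiles round to zero components contributes 0.
    """
    ref = np.asarray(ref, float)
    est = np.asarray(est, float)
    if ref.shape != est.shape:
        raise InvalidInputError("count profiles must share one length")
    denom = np.maximum(ref, est)
    with np.errstate(divide="ignore", invalid="ignore"):
        err = np.abs(ref - est) / denom
    err[denom == 0] = 0.0
    err[(np.floor(ref + 0.5) == 0) & (np.floor(est + 0.5) == 0)] = 0.0
    return err


def lre_error(
    reference: TFDGrid, estimate: RidgeMap, params: LocalizationParams
) -> tuple[float, float, float, float, float, float]:
    """LRE-based (mse_t, mse_f, mse_tf, mae_t, mae_f, mae_tf).

    Both grids are run through the same STRE/NBRE counters; the
    normalized per-slice differences are averaged per axis and across
    axes.
    """
    if reference.values.shape != estimate.values.shape:
        raise InvalidInputError("reference and estimate shapes differ")
    est_grid = estimate.as_grid()
    err_t = normalized_count_error(
        params.counts_time(reference).counts, params.counts_time(est_grid).counts
    )
    err_f = normalized_count_error(
        params.counts_freq(reference).counts, params.counts_freq(est_grid).counts
    )
    mse_t, mse_f = float(np.mean(err_t**2)), float(np.mean(err_f**2))
    mae_t, mae_f = float(np.mean(err_t)), float(np.mean(err_f))
    return mse_t, mse_f, (mse_t + mse_f) / 2, mae_t, mae_f, (mae_t + mae_f) / 2


def f1_score(
    estimate: RidgeMap,
    truth_if: np.ndarray,
    truth_gd: np.ndarray | None = None,
    tol: int = 1,
) -> tuple[float, float, float]:
    """(precision, recall, f1) of estimated pixels against ideal ridges.

    ``truth_if`` is an (n, 2) array of (time, frequency-bin) ridge
    pixels matched within +/- ``tol`` frequency bins at the same time
    instant; ``truth_gd`` pixels (spike columns) match within +/- ``tol``
    time samples at the same bin.  Each truth sample is matched at most
    once.  Zero denominators yield 0 by convention.
    """
    est_pixels = sorted((int(t), int(f)) for t, f in zip(*np.nonzero(estimate.values)))
    truth_if = np.asarray(truth_if, int).reshape(-1, 2)
    truth_gd = (np.zeros((0, 2), int) if truth_gd is None
                else np.asarray(truth_gd, int).reshape(-1, 2))
    unmatched_if = {tuple(p) for p in truth_if}
    unmatched_gd = {tuple(p) for p in truth_gd}
    tp = 0
    for t, f in est_pixels:
        hit = None
        for df in sorted(range(-tol, tol + 1), key=abs):
            if (t, f + df) in unmatched_if:
                hit = ("if", (t, f + df))
                break
        if hit is None:
            for dt in sorted(range(-tol, tol + 1), key=abs):
                if (t + dt, f) in unmatched_gd:
                    hit = ("gd", (t + dt, f))
                    break
        if hit is None:
            continue
        tp += 1
        (unmatched_if if hit[0] == "if" else unmatched_gd).discard(hit[1])
    fp = len(est_pixels) - tp
    fn = len(unmatched_if) + len(unmatched_gd)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def fnorm(a: RidgeMap, b: RidgeMap) -> float:
    """Scaled squared Frobenius norm of the difference of two maps."""
    if a.values.shape != b.values.shape:
        raise InvalidInputError("maps must share one shape")
    diff = a.values.astype(float) - b.values.astype(float)
    return float(np.sum(diff**2) / diff.size)


def count_profile_mse(clean: LocalCountProfile, noisy: LocalCountProfile) -> float:
    """Mean normalized squared difference between two count profiles."""
    if clean.axis != noisy.axis or len(clean) != len(noisy):
        raise InvalidInputError("profiles must share one axis and length")
    err = normalized_count_error(clean.counts, noisy.counts)
    return float(np.mean(err**2))
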