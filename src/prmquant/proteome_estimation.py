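"""Transcript-based proteome-wide abundance estimation.

TPM from gene-level counts, an ordinary-least-squares fit of
log10(copies/cell) on log10(TPM), proteome-wide prediction from the fitted
line, and symmetric fold-error summaries of modeled vs measured values.
Base-10 logarithms throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("prmquant")

__all__ = [
    "RegressionModel",
    "FoldErrorSummary",
    "compute_tpm",
    "fit_loglog",
    "predict_proteome",
    "fold_error_summary",
]


@dataclass(frozen=True)
class RegressionModel:
    """OLS fit of log10(copies/cell) on log10(TPM)."""

    slope: float
    intercept: float
    r: float
    r_squared: float
    n_points: int
    slope_stderr: float = math.nan
    intercept_stderr: float = math.nan

    def predict_log10_copies(self, log10_tpm: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(log10_tpm, dtype=float) + self.intercept


@dataclass(frozen=True)
class FoldErrorSummary:
    mean: float
    geometric_mean: float
    median: float
    ratios: tuple[float, ...]


def compute_tpm(counts, effective_lengths) -> np.ndarray:
    """Transcripts per million: length-normalized rates scaled to sum to 1e6."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(effective_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    return 1e6 * rates / total


def fit_loglog(tpm_measured, copies_measured) -> RegressionModel:
    """OLS of log10(copies) on log10(TPM) over pairs with both values positive.

    Pairs with a zero in either coordinate are excluded (log undefined) and
    their count is logged.  Requires >=3 usable pairs and predictor variance.
    """
    tpm = np.asarray(tpm_measured, dtype=float)
    copies = np.asarray(copies_measured, dtype=float)
    if tpm.shape != copies.shape:
        raise ValueError("tpm and copies must be the same length")
    usable = (tpm > 0) & (copies > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("fit_loglog: %d pair(s) with nonpositive values excluded", n_dropped)
    x = np.log10(tpm[usable])
    y = np.log10(copies[usable])
    if x.size < 3:
        raise ValueError(f"need >=3 positive pairs, have {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10(TPM)")
    fit = stats.linregress(x, y)
    # stderr of the intercept: s * sqrt(1/n + xbar^2/Sxx)
    return RegressionModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        n_points=int(x.size),
        slope_stderr=float(fit.stderr),
        intercept_stderr=float(fit.intercept_stderr),
    )


def predict_proteome(tpm_all: pd.DataFrame, model: RegressionModel) -> pd.DataFrame:
    """Estimate copies/cell for every gene with TPM > 0.

    ``tpm_all`` needs columns ``gene`` and ``tpm``.  Genes with TPM = 0 are
    emitted with NaN estimates and ``estimable = False``.
    """
    frame = tpm_all[["gene", "tpm"]].copy()
    positive = frame["tpm"] > 0
    estimates = np.full(len(frame), np.nan)
    estimates[positive.to_numpy()] = 10 ** model.predict_log10_copies(
        np.log10(frame.loc[positive, "tpm"].to_numpy())
    )
    frame["estimated_copies_per_cell"] = estimates
    frame["estimable"] = positive
    return frame


def fold_error_summary(modeled, measured) -> FoldErrorSummary:
    """Symmetric per-gene fold errors: max(m/x, x/m), summarized three ways."""
    modeled = np.asarray(modeled, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if modeled.shape != measured.shape:
        raise ValueError("modeled and measured must be the same length")
    if modeled.size == 0:
        raise ValueError("empty input")
    if (modeled <= 0).any() or (measured <= 0).any():
        raise ValueError("fold errors need strictly positive pairs")
    direct = modeled / measured
    ratios = np.maximum(direct, 1.0 / direct)
    return FoldErrorSummary(
        mean=float(ratios.mean()),
        geometric_mean=float(np.exp(np.mean(np.log(ratios)))),
        median=float(np.median(ratios)),
        ratios=tuple(float(r) for r in ratios),
    )
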