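"""Subject-specific diurnal distributional curves.

For each time-of-day bin (default 10 minutes, 144 bins) all wear minutes of
a subject are pooled across days — ignoring day and within-bin position —
and summarized by a distributional metric: mean, mode, SD, MAD, coefficient
of variation, or an upper quantile (q50, q90, q95, q99, q100 = maximum).
The resulting length-S vector, indexed by bin midpoint on the [0, 24] hour
domain, is the functional covariate of the scalar-on-function regression.

Conventions (all configurable):
  * quantiles default to the inverse-empirical-CDF estimator (lower order
    statistic), so they are observed values and commute with the monotone
    AC -> LAC transform;
  * SD uses the pooled-denominator (population-style) formula;
  * mode is the most frequent integer AC value, ties to the smallest; on
    the LAC scale it is the transform of the AC mode;
  * CV = SD/mean, set to 0 when mean or SD is at or below a threshold c
    (default 0);
  * bins left empty by non-wear are filled by circular linear interpolation
    and flagged; a subject with > 50% empty bins is marked invalid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, JoinError, ScaleError
from .preprocess import MINUTES_PER_DAY, SubjectDayMatrix, log_transform

logger = logging.getLogger(__name__)

METRICS = ("mean", "mode", "sd", "mad", "cv",
           "q50", "q90", "q95", "q99", "q100")
_QUANTILE_LEVEL = {"q50": 0.50, "q90": 0.90, "q95": 0.95,
                   "q99": 0.99, "q100": 1.00}


@dataclass
class BinGrid:
    """Partition of the 1440-minute day into equal bins."""

    bin_width_minutes: int = 10

    def __post_init__(self):
        if MINUTES_PER_DAY % self.bin_width_minutes != 0:
            raise DimensionError(
                f"bin width must divide {MINUTES_PER_DAY}, got {self.bin_width_minutes}")

    @property
    def n_bins(self) -> int:
        return MINUTES_PER_DAY // self.bin_width_minutes

    @property
    def midpoints_hours(self) -> np.ndarray:
        w = self.bin_width_minutes / 60.0
        return (np.arange(self.n_bins) + 0.5) * w

    @property
    def width_hours(self) -> float:
        return self.bin_width_minutes / 60.0


@dataclass
class DiurnalCurve:
    """One distributional metric of one subject over the S bins."""

    subject_id: str
    metric: str
    scale: str
    values: np.ndarray
    support: np.ndarray                    # contributing minutes per bin
    imputed_bins: np.ndarray = None        # bins filled by interpolation
    valid: bool = True
    reason: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        if self.imputed_bins is None:
            self.imputed_bins = np.zeros(self.values.size, dtype=bool)


# ---------------------------------------------------------------------------
# pooling and scalar summaries
# ---------------------------------------------------------------------------

def _masked_values(matrix: SubjectDayMatrix) -> np.ndarray:
    """Counts with non-wear minutes replaced by NaN (excluded from pools)."""
    return np.where(matrix.wear_mask, matrix.counts, np.nan)


def pool_bin(matrix: SubjectDayMatrix, grid: BinGrid, s: int) -> np.ndarray:
    """All wear-minute values of bin ``s`` pooled across the retained days."""
    if not 0 <= s < grid.n_bins:
        raise DimensionError(f"bin index {s} outside 0..{grid.n_bins - 1}")
    w = grid.bin_width_minutes
    vals = _masked_values(matrix)[:, s * w:(s + 1) * w].ravel()
    return vals[~np.isnan(vals)]


def _mode_int(pool: np.ndarray) -> float:
    """Most frequent value; ties broken by the smallest value."""
    vals, counts = np.unique(pool, return_counts=True)
    return float(vals[np.argmax(counts)])  # np.unique sorts ascending


def bin_summary(pool, metric: str, *, quantile_type: str = "lower",
                cv_threshold: float = 0.0, sd_denominator: str = "pooled",
                scale: str = "AC") -> float:
    """One scalar summary of a pooled bin sample; NaN on an empty pool."""
    pool = np.asarray(pool, dtype=float)
    pool = pool[~np.isnan(pool)]
    if pool.size == 0:
        return float("nan")
    if metric == "mean":
        return float(pool.mean())
    if metric == "sd":
        ddof = 0 if sd_denominator == "pooled" else 1
        if pool.size - ddof <= 0:
            return 0.0
        return float(np.sqrt(np.sum((pool - pool.mean()) ** 2) / (pool.size - ddof)))
    if metric == "mad":
        return float(np.median(np.abs(pool - np.median(pool))))
    if metric == "cv":
        mu = pool.mean()
        sd = bin_summary(pool, "sd", sd_denominator=sd_denominator)
        if mu <= cv_threshold or sd <= cv_threshold:
            return 0.0
        return float(sd / mu)
    if metric == "mode":
        if scale == "LAC":
            return float(np.log1p(_mode_int(np.rint(np.expm1(pool)))))
        return _mode_int(np.rint(pool))
    if metric in _QUANTILE_LEVEL:
        method = "inverted_cdf" if quantile_type == "lower" else "linear"
        return float(np.quantile(pool, _QUANTILE_LEVEL[metric], method=method))
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# full curves
# ---------------------------------------------------------------------------

def _circular_fill(values: np.ndarray) -> np.ndarray:
    """Linear interpolation of NaN entries on a circular index domain."""
    out = values.copy()
    nan = np.isnan(out)
    if not nan.any() or nan.all():
        return out
    S = out.size
    idx = np.arange(S)
    good = idx[~nan]
    xp = np.r_[good - S, good, good + S]
    fp = np.tile(out[~nan], 3)
    out[nan] = np.interp(idx[nan], xp, fp)
    return out


def compute_curves(matrix: SubjectDayMatrix, grid: BinGrid, metrics=METRICS,
                   *, quantile_type: str = "lower", cv_threshold: float = 0.0,
                   sd_denominator: str = "pooled",
                   max_empty_fraction: float = 0.5) -> dict:
    """All requested metrics for one subject, sharing one pooling pass."""
    S, w = grid.n_bins, grid.bin_width_minutes
    D = matrix.n_days
    pools = _masked_values(matrix).reshape(D, S, w).transpose(1, 0, 2).reshape(S, D * w)
    support = (~np.isnan(pools)).sum(axis=1)
    empty = support == 0
    valid = empty.mean() <= max_empty_fraction
    reason = "" if valid else (
        f"{empty.sum()}/{S} empty bins exceeds {max_empty_fraction:.0%}")
    if not valid:
        logger.warning("subject %s flagged: %s", matrix.subject_id, reason)

    out = {}
    method = "inverted_cdf" if quantile_type == "lower" else "linear"
    qmetrics = [m for m in metrics if m in _QUANTILE_LEVEL]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(pools, axis=1)
        sd_ddof = 0 if sd_denominator == "pooled" else 1
        if sd_ddof == 0:
            sd = np.sqrt(np.nanmean((pools - mean[:, None]) ** 2, axis=1))
        else:
            sd = np.nanstd(pools, axis=1, ddof=1)
        med = np.nanmedian(pools, axis=1)
        mad = np.nanmedian(np.abs(pools - med[:, None]), axis=1)
        qvals = {}
        if qmetrics:
            qq = np.nanquantile(pools, [_QUANTILE_LEVEL[m] for m in qmetrics],
                                axis=1, method=method)
            qvals = dict(zip(qmetrics, qq))

    for metric in metrics:
        if metric == "mean":
            vals = mean.copy()
        elif metric == "sd":
            vals = sd.copy()
        elif metric == "mad":
            vals = mad.copy()
        elif metric == "cv":
            vals = np.where((mean > cv_threshold) & (sd > cv_threshold),
                            sd / np.where(mean > 0, mean, 1.0), 0.0)
            vals[empty] = np.nan
        elif metric == "mode":
            vals = np.full(S, np.nan)
            for s in range(S):
                p = pools[s][~np.isnan(pools[s])]
                if p.size:
                    vals[s] = bin_summary(p, "mode", scale=matrix.scale)
        elif metric in _QUANTILE_LEVEL:
            vals = qvals[metric].copy()
        else:
            raise ValueError(f"unknown metric {metric!r}")
        vals = _circular_fill(vals)
        out[metric] = DiurnalCurve(
            subject_id=matrix.subject_id, metric=metric, scale=matrix.scale,
            values=vals, support=support, imputed_bins=empty.copy(),
            valid=valid, reason=reason)
    return out


def compute_curve(matrix: SubjectDayMatrix, grid: BinGrid, metric: str,
                  **options) -> DiurnalCurve:
    """Single-metric convenience wrapper over :func:`compute_curves`."""
    return compute_curves(matrix, grid, metrics=(metric,), **options)[metric]


def curve_matrix(matrices, covariates: pd.DataFrame, grid: BinGrid, metric: str,
                 scale: str = "AC", **options):
    """Stack per-subject curves as an n x S matrix aligned with the covariates.

    Rows follow covariate-table order.  Subjects excluded upstream (missing
    from ``matrices`` or flagged invalid) are dropped; a curve subject absent
    from the covariate table is an error.
    """
    if scale not in ("AC", "LAC"):
        raise ScaleError(f"scale must be AC or LAC, got {scale!r}")
    cov_ids = list(covariates["subject_id"])
    curve_by_id = {}
    for m in matrices:
        mm = m
        if scale == "LAC" and m.scale == "AC":
            mm = log_transform(m)
        elif mm.scale != scale:
            raise ScaleError(f"matrix {m.subject_id} on scale {m.scale}, "
                             f"cannot produce {scale}")
        c = compute_curve(mm, grid, metric, **options)
        if not c.valid:
            logger.warning("dropping subject %s from %s/%s matrix: %s",
                           m.subject_id, metric, scale, c.reason)
            continue
        curve_by_id[m.subject_id] = c
    orphans = sorted(set(curve_by_id) - set(cov_ids))
    if orphans:
        raise JoinError(f"curve subjects missing from covariates: {orphans}")
    ids = [sid for sid in cov_ids if sid in curve_by_id]
    mat = np.vstack([curve_by_id[sid].values for sid in ids]) if ids else \
        np.empty((0, grid.n_bins))
    return mat, ids


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_curve_matrix(mat: np.ndarray, ids, grid: BinGrid, path,
                       metadata_path=None, **meta) -> None:
    """Curve matrix as CSV with HH:MM bin-start columns + metadata JSON."""
    starts = np.arange(grid.n_bins) * grid.bin_width_minutes
    cols = [f"{t // 60:02d}:{t % 60:02d}" for t in starts]
    df = pd.DataFrame(mat, columns=cols)
    df.insert(0, "subject_id", ids)
    df.to_csv(path, index=False, float_format="%.10g")
    if metadata_path is not None:
        import json
        meta.setdefault("bin_width_minutes", grid.bin_width_minutes)
        with open(metadata_path, "w") as fh:
            json.dump(meta, fh, indent=1)
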