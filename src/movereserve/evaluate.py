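"""Repeated cross-validated R2 comparison, scalar biomarkers, stratification.

The discriminative power of each diurnal curve type is scored by 5-fold
cross-validation repeated 100 times (defaults): per replication a random
fold partition is drawn on shuffled subject IDs, the full SOFR fit —
including smoothing-parameter selection — is repeated on each training set,
and the replication R2 pools held-out predictions,
R2 = 1 - SSE/SST with the full-sample mean as baseline.  Within a
replication every metric sees identical fold partitions, so metric
comparisons are paired.  The 95% CI is the 2.5/97.5 percentile interval of
the replication R2 values.

Scalar biomarkers integrate the estimated coefficient function against each
subject's curve, BM_i = integral beta-hat(s) R_i(s) ds — exactly the fitted
functional-term contribution — and can be summarized across disability
strata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import BinGrid, curve_matrix
from .errors import DimensionError, GridMismatchError
from .sofr import (BSplineBasis, QuadratureSpec, SofrFit, build_design,
                   fit_sofr, predict)

logger = logging.getLogger(__name__)


@dataclass
class CVResult:
    """Per-replication held-out R2 values for one metric/scale."""

    metric: str
    scale: str
    r2: np.ndarray
    k: int
    seed: int

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)

    @property
    def reps(self) -> int:
        return self.r2.size

    @property
    def mean_r2(self) -> float:
        return float(self.r2.mean())

    @property
    def ci(self) -> tuple:
        return (float(np.percentile(self.r2, 2.5)),
                float(np.percentile(self.r2, 97.5)))

    def to_json(self, path) -> None:
        import json
        lo, hi = self.ci
        with open(path, "w") as fh:
            json.dump({"metric": self.metric, "scale": self.scale,
                       "k": self.k, "reps": self.reps, "seed": self.seed,
                       "mean_r2": self.mean_r2, "ci_low": lo, "ci_high": hi,
                       "r2": self.r2.tolist()}, fh, indent=1)


# ---------------------------------------------------------------------------
# fold machinery
# ---------------------------------------------------------------------------

def fold_assignments(ids, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold label per input row, assigned on shuffled sorted-ID order.

    Sorting before shuffling makes the partition a function of the ID set
    and the seed only, never of row order.  Fold sizes differ by at most
    one (remainder subjects spread one per fold).
    """
    ids = np.asarray(ids)
    order = np.argsort(ids, kind="stable")
    perm = rng.permutation(ids.size)
    labels_sorted = np.empty(ids.size, dtype=int)
    base, rem = divmod(ids.size, k)
    sizes = [base + (1 if f < rem else 0) for f in range(k)]
    pos = 0
    for f, sz in enumerate(sizes):
        labels_sorted[perm[pos:pos + sz]] = f
        pos += sz
    labels = np.empty(ids.size, dtype=int)
    labels[order] = labels_sorted
    return labels


def _cv_r2_one_rep(y, Z, F, P, labels, k, lambda_rule):
    """Pooled held-out R2 for one fold partition (full refit per fold)."""
    yhat = np.empty_like(y)
    for f in range(k):
        test = labels == f
        train = ~test
        fit = fit_sofr(y[train], Z[train], F[train], P, lambda_rule=lambda_rule)
        yhat[test] = Z[test] @ fit.alpha + F[test] @ fit.beta_coefs
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - sse / sst


def cross_validate(y, curves, covariates, *, k: int = 5, reps: int = 100,
                   seed: int = 0, basis: BSplineBasis = None,
                   quad: QuadratureSpec = None, lambda_rule="gcv",
                   metric: str = "", scale: str = "",
                   fold_labels: list = None) -> CVResult:
    """Repeated k-fold cross-validated R2 of the SOFR model.

    ``fold_labels`` (one label array per replication) lets callers share
    partitions across metrics; otherwise partitions derive from ``seed``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if basis is None:
        basis = BSplineBasis()
    if quad is None:
        quad = QuadratureSpec.from_bingrid(BinGrid())
    if n < 2 * k:
        k = max(n // 2, 2)
        warnings.warn(f"too few subjects for requested folds; k reduced to {k}",
                      RuntimeWarning)
    min_train = basis.K + 5
    while k > 2 and n - int(np.ceil(n / k)) < min_train:
        k -= 1
        warnings.warn(f"training folds too small; k reduced to {k}", RuntimeWarning)
    Z, F, P = build_design(curves, covariates, basis, quad)
    ids = (covariates["subject_id"].to_numpy()
           if hasattr(covariates, "columns") and "subject_id" in covariates
           else np.arange(n))
    if fold_labels is None:
        rngs = [np.random.default_rng(s)
                for s in np.random.SeedSequence(seed).spawn(reps)]
        fold_labels = [fold_assignments(ids, k, rng) for rng in rngs]
    r2 = np.array([_cv_r2_one_rep(y, Z, F, P, lab, k, lambda_rule)
                   for lab in fold_labels])
    return CVResult(metric=metric, scale=scale, r2=r2, k=k, seed=seed)


# ---------------------------------------------------------------------------
# metric-comparison grid
# ---------------------------------------------------------------------------

def metric_comparison(matrices, covariates: pd.DataFrame, *,
                      metrics=("mean", "mode", "sd", "mad", "cv",
                               "q50", "q90", "q95", "q99", "q100"),
                      scales=("AC", "LAC"), grid: BinGrid = None,
                      k: int = 5, reps: int = 100, seed: int = 0,
                      basis: BSplineBasis = None, lambda_rule="gcv",
                      curve_options: dict = None):
    """One repeated-CV result per metric x scale with shared fold partitions.

    Returns (table DataFrame with mean R2 and percentile CI, dict of
    CVResult keyed by (metric, scale)).  Fold partitions are identical
    across metrics within a replication, so comparisons are paired.
    """
    if grid is None:
        grid = BinGrid()
    if basis is None:
        basis = BSplineBasis()
    quad = QuadratureSpec.from_bingrid(grid)
    curve_options = curve_options or {}
    y = covariates["EDSS"].to_numpy(dtype=float)

    # build all curve matrices first so every metric sees the same subjects
    mats, skipped = {}, []
    for scale in scales:
        for metric in metrics:
            try:
                cm, ids = curve_matrix(matrices, covariates, grid, metric,
                                       scale=scale, **curve_options)
            except Exception as exc:  # listed and skipped, not fatal
                logger.warning("skipping %s/%s: %s", metric, scale, exc)
                skipped.append((metric, scale, str(exc)))
                continue
            mats[(metric, scale)] = (cm, ids)
    common_ids = None
    for cm, ids in mats.values():
        common_ids = set(ids) if common_ids is None else common_ids & set(ids)
    if not mats:
        return pd.DataFrame(), {}
    keep_ids = [sid for sid in covariates["subject_id"] if sid in common_ids]
    cov = covariates.set_index("subject_id").loc[keep_ids].reset_index()
    y = cov["EDSS"].to_numpy(dtype=float)
    n = len(keep_ids)

    k_eff = k
    min_train = basis.K + 5
    while k_eff > 2 and n - int(np.ceil(n / k_eff)) < min_train:
        k_eff -= 1
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(reps)]
    shared_labels = [fold_assignments(np.asarray(keep_ids), k_eff, rng)
                     for rng in rngs]

    results, rows = {}, []
    for (metric, scale), (cm, ids) in mats.items():
        sel = {sid: i for i, sid in enumerate(ids)}
        cm = cm[[sel[sid] for sid in keep_ids]]
        res = cross_validate(y, cm, cov, k=k_eff, reps=reps, seed=seed,
                             basis=basis, quad=quad, lambda_rule=lambda_rule,
                             metric=metric, scale=scale,
                             fold_labels=shared_labels)
        results[(metric, scale)] = res
        lo, hi = res.ci
        rows.append({"metric": metric, "scale": scale, "mean_r2": res.mean_r2,
                     "ci_low": lo, "ci_high": hi, "k": res.k, "reps": res.reps})
    table = pd.DataFrame(rows).sort_values(
        ["scale", "metric"]).reset_index(drop=True)
    return table, results


def comparison_markdown(table: pd.DataFrame) -> str:
    """Render the comparison table as Markdown, one row per metric."""
    scales = list(dict.fromkeys(table["scale"]))
    lines = ["| metric | " + " | ".join(f"{s} R2 (95% CI)" for s in scales) + " |",
             "|---" * (len(scales) + 1) + "|"]
    for metric in dict.fromkeys(table["metric"]):
        cells = []
        for s in scales:
            row = table[(table.metric == metric) & (table.scale == s)]
            if row.empty:
                cells.append("—")
            else:
                r = row.iloc[0]
                cells.append(f"{r.mean_r2:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f})")
        lines.append(f"| {metric} | " + " | ".join(cells) + " |")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# biomarkers
# ---------------------------------------------------------------------------

def compute_biomarker(fit: SofrFit, curves: np.ndarray, ids,
                      metric: str = "") -> pd.DataFrame:
    """BM_i = integral beta-hat(s) R_i(s) ds, per subject.

    Equals the fitted functional-term contribution, so predict() decomposes
    exactly as Z alpha-hat + BM.
    """
    curves = np.asarray(curves, dtype=float)
    if fit.quad is None or curves.shape[1] != fit.quad.grid.size:
        raise GridMismatchError("curves and fit disagree on the bin grid")
    beta_s = fit.beta(fit.quad.grid)
    bm = curves @ (fit.quad.weights * beta_s)
    return pd.DataFrame({"subject_id": list(ids), "metric": metric,
                         "biomarker": bm})


def stratify_biomarker(table: pd.DataFrame, edss: pd.Series | dict,
                       threshold: float = 4.0) -> pd.DataFrame:
    """Summaries of the biomarker below/above an EDSS threshold.

    The threshold is an analysis choice; 4.0 (ambulation limit) and 6.0
    (assistance to walk) are conventional MS cutpoints.
    """
    t = table.copy()
    edss_map = dict(edss) if not isinstance(edss, pd.Series) else edss.to_dict()
    t["EDSS"] = t["subject_id"].map(edss_map)
    if t["EDSS"].isna().any():
        missing = t.loc[t["EDSS"].isna(), "subject_id"].tolist()
        raise DimensionError(f"no EDSS for subjects: {missing}")
    t["stratum"] = np.where(t["EDSS"] <= threshold,
                            f"EDSS<={threshold}", f"EDSS>{threshold}")
    rows = []
    for (metric, stratum), g in t.groupby(["metric", "stratum"]):
        v = g["biomarker"].to_numpy()
        rows.append({"metric": metric, "stratum": stratum, "n": v.size,
                     "mean": v.mean(), "sd": v.std(ddof=1) if v.size > 1 else np.nan,
                     "q25": np.percentile(v, 25), "median": np.median(v),
                     "q75": np.percentile(v, 75)})
    # report empty strata explicitly
    for metric in t["metric"].unique():
        present = {r["stratum"] for r in rows if r["metric"] == metric}
        for stratum in (f"EDSS<={threshold}", f"EDSS>{threshold}"):
            if stratum not in present:
                rows.append({"metric": metric, "stratum": stratum, "n": 0,
                             "mean": np.nan, "sd": np.nan, "q25": np.nan,
                             "median": np.nan, "q75": np.nan})
    return pd.DataFrame(rows).sort_values(["metric", "stratum"]).reset_index(drop=True)
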