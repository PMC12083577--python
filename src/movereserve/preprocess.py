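"""Quality control of minute-epoch actigraphy.

Raw records are minute-of-day activity counts (AC), one row per observed
minute.  Preprocessing turns them into complete per-subject day x 1440
matrices via a fixed rule order:

    DST normalization -> final-hour / residual-minute imputation ->
    non-wear detection -> valid-day filter -> subject filter ->
    (optional) log transform.

Non-wear is any maximal run of >= 90 consecutive zero-count minutes; a valid
day has >= 90% wear time (imputed minutes count as wear); subjects need at
least three valid days.  Daylight-saving days are normalized by same-minute
averaging: a spring (short) day has its missing hour imputed from the
subject's other days, a fall (long) day has its duplicated hour averaged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import DimensionError, ImputationError, ScaleError

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440
NONWEAR_MIN_RUN = 90          # minutes of consecutive zeros flagged device-off
WEAR_FRACTION = 0.9           # valid-day threshold (inclusive: >= 1296 min)
MIN_VALID_DAYS = 3


@dataclass
class DayRecord:
    """Observed minutes of a single day, possibly incomplete or duplicated.

    ``minutes`` holds minute-of-day labels (0-1439), sorted, with DST-fall
    duplicates adjacent; ``values`` the corresponding counts.
    """

    minutes: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.minutes = np.asarray(self.minutes, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.minutes.shape != self.values.shape:
            raise DimensionError("minutes and values must have equal length")

    @property
    def n_observed(self) -> int:
        return int(self.minutes.size)


@dataclass
class SubjectDayMatrix:
    """Per-subject stack of day x 1440 minute counts with a wear mask.

    ``counts`` may contain NaN before imputation (absent minutes).  DST-fall
    duplicate hours that do not fit the rectangular layout are carried in
    ``duplicate_hours`` (day index -> DayRecord of the second copies) until
    :func:`preprocess_cohort` averages them in.
    """

    subject_id: str
    days: list
    counts: np.ndarray
    wear_mask: np.ndarray = None
    scale: str = "AC"
    duplicate_hours: dict = field(default_factory=dict)
    imputed: np.ndarray = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != MINUTES_PER_DAY:
            raise DimensionError(
                f"counts must be n_days x {MINUTES_PER_DAY}, got {self.counts.shape}"
            )
        if len(self.days) != self.counts.shape[0]:
            raise DimensionError("days list does not match counts rows")
        if self.wear_mask is None:
            self.wear_mask = np.ones_like(self.counts, dtype=bool)
        else:
            self.wear_mask = np.asarray(self.wear_mask, dtype=bool)
            if self.wear_mask.shape != self.counts.shape:
                raise DimensionError("wear_mask shape must match counts")
        if self.imputed is None:
            self.imputed = np.zeros_like(self.counts, dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)
        if self.scale not in ("AC", "LAC"):
            raise ScaleError(f"scale must be 'AC' or 'LAC', got {self.scale!r}")

    @property
    def n_days(self) -> int:
        return self.counts.shape[0]

    def copy(self) -> "SubjectDayMatrix":
        return SubjectDayMatrix(
            subject_id=self.subject_id,
            days=list(self.days),
            counts=self.counts.copy(),
            wear_mask=self.wear_mask.copy(),
            scale=self.scale,
            duplicate_hours={
                d: DayRecord(r.minutes.copy(), r.values.copy())
                for d, r in self.duplicate_hours.items()
            },
            imputed=self.imputed.copy(),
        )


@dataclass
class QCReport:
    """Per-day wear fractions, valid-day flags, exclusions and DST log."""

    wear_fraction: dict = field(default_factory=dict)     # sid -> [float]
    valid_days: dict = field(default_factory=dict)        # sid -> [bool]
    excluded: dict = field(default_factory=dict)          # sid -> reason
    dst_adjusted: dict = field(default_factory=dict)      # sid -> [(date, mode)]
    n_input: int = 0
    n_retained: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)

    def summary(self) -> str:
        lines = [
            f"subjects in: {self.n_input}",
            f"subjects retained: {self.n_retained}",
            f"subjects excluded: {len(self.excluded)}",
        ]
        for sid, reason in sorted(self.excluded.items()):
            lines.append(f"  - {sid}: {reason}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# non-wear and valid-day rules
# ---------------------------------------------------------------------------

def detect_nonwear(day_counts, min_run: int = NONWEAR_MIN_RUN) -> np.ndarray:
    """Wear mask for one complete day: False on runs of >= min_run zeros.

    Depends only on the zero pattern, never on count magnitudes.  NaN values
    (not expected after imputation) break zero runs.
    """
    z = np.asarray(day_counts, dtype=float)
    if z.ndim != 1 or z.size != MINUTES_PER_DAY:
        raise DimensionError(
            f"expected a {MINUTES_PER_DAY}-minute day, got length {z.size}"
        )
    iszero = z == 0  # NaN compares False
    wear = np.ones(z.size, dtype=bool)
    padded = np.r_[False, iszero, False]
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            wear[s:e] = False
    return wear


def is_valid_day(wear_mask, wear_fraction: float = WEAR_FRACTION) -> bool:
    """True iff the day has at least ``wear_fraction`` wear minutes (inclusive)."""
    mask = np.asarray(wear_mask, dtype=bool)
    if mask.ndim != 1 or mask.size != MINUTES_PER_DAY:
        raise DimensionError(f"wear mask must have length {MINUTES_PER_DAY}")
    threshold = int(np.ceil(wear_fraction * mask.size - 1e-9))
    return int(mask.sum()) >= threshold


# ---------------------------------------------------------------------------
# DST normalization and imputation
# ---------------------------------------------------------------------------

def _provisional_wear(day_counts: np.ndarray) -> np.ndarray:
    """Non-wear scan tolerant of missing minutes (NaN breaks zero runs)."""
    filled = np.where(np.isnan(day_counts), -1.0, day_counts)
    return detect_nonwear(filled)


def donor_minute_means(matrix: SubjectDayMatrix, exclude_day: int) -> np.ndarray:
    """Same-minute mean over the subject's other days.

    Donor minutes that are missing or fall in a donor-day non-wear run are
    excluded.  Returns NaN where no donor minute is available.
    """
    donors = [d for d in range(matrix.n_days) if d != exclude_day]
    if not donors:
        return np.full(MINUTES_PER_DAY, np.nan)
    vals = matrix.counts[donors]
    ok = ~np.isnan(vals)
    for row, d in enumerate(donors):
        ok[row] &= _provisional_wear(matrix.counts[d])
    with np.errstate(invalid="ignore"):
        s = np.where(ok, vals, 0.0).sum(axis=0)
        n = ok.sum(axis=0)
        out = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return out


def normalize_dst(record: DayRecord, mode: str,
                  donor_mean: np.ndarray | None = None) -> np.ndarray:
    """Reduce a DST-shifted day record to a complete 1440-minute day.

    ``spring``: the 60 absent minutes are filled with the subject's same-minute
    mean across other days (``donor_mean``).  ``fall``: the two copies of each
    duplicated minute are averaged.
    """
    if mode not in ("spring", "fall"):
        raise ValueError(f"mode must be 'spring' or 'fall', got {mode!r}")
    day = np.full(MINUTES_PER_DAY, np.nan)
    if mode == "fall":
        # average all copies of each minute label
        sums = np.zeros(MINUTES_PER_DAY)
        cnt = np.zeros(MINUTES_PER_DAY)
        np.add.at(sums, record.minutes, record.values)
        np.add.at(cnt, record.minutes, 1.0)
        observed = cnt > 0
        day[observed] = sums[observed] / cnt[observed]
    else:
        day[record.minutes] = record.values
    missing = np.isnan(day)
    if missing.any():
        if donor_mean is None:
            raise ImputationError("spring day needs donor means for the missing hour")
        fill = np.asarray(donor_mean, dtype=float)[missing]
        if np.isnan(fill).any():
            raise ImputationError("no donor day covers part of the missing hour")
        day[missing] = fill
    return day


def _impute_missing(matrix: SubjectDayMatrix, day: int) -> None:
    """In place: fill NaN minutes of one day from donor means; mark imputed."""
    missing = np.isnan(matrix.counts[day])
    if not missing.any():
        return
    donor = donor_minute_means(matrix, exclude_day=day)
    fill = donor[missing]
    if np.isnan(fill).any():
        raise ImputationError(
            f"subject {matrix.subject_id}, day {matrix.days[day]}: "
            "no donor day covers some missing minutes"
        )
    matrix.counts[day, missing] = fill
    matrix.imputed[day, missing] = True


def impute_final_hour(matrix: SubjectDayMatrix) -> SubjectDayMatrix:
    """Impute any missing minutes on the last recorded day (same-minute mean)."""
    out = matrix.copy()
    last = out.n_days - 1
    _impute_missing(out, last)
    return out


def log_transform(matrix: SubjectDayMatrix) -> SubjectDayMatrix:
    """AC -> LAC via x -> ln(x + 1); preserves the order of values."""
    if matrix.scale != "AC":
        raise ScaleError("log_transform expects an AC-scale matrix")
    out = matrix.copy()
    out.counts = np.log1p(out.counts)
    out.scale = "LAC"
    return out


# ---------------------------------------------------------------------------
# cohort-level pipeline
# ---------------------------------------------------------------------------

def apply_nonwear(matrix: SubjectDayMatrix, min_run: int = NONWEAR_MIN_RUN,
                  policy: str = "exclude") -> np.ndarray:
    """Set the matrix wear mask from the zero-run rule; return detected mask.

    Imputed minutes always count as wear.  With ``policy='include-as-zero'``
    the exported mask stays all-True (non-wear zeros enter downstream bins)
    while the returned detected mask still drives valid-day QC.
    """
    detected = np.vstack([detect_nonwear(matrix.counts[d], min_run)
                          for d in range(matrix.n_days)])
    detected |= matrix.imputed
    matrix.wear_mask = np.ones_like(detected) if policy == "include-as-zero" else detected.copy()
    return detected


def filter_cohort(matrices, min_valid_days: int = MIN_VALID_DAYS,
                  wear_fraction: float = WEAR_FRACTION,
                  report: QCReport | None = None):
    """Drop invalid days; exclude subjects with too few valid days.

    Expects wear masks already set (see :func:`apply_nonwear`).  Returns
    (retained matrices, QCReport).
    """
    if report is None:
        report = QCReport()
    report.n_input = len(matrices)
    retained = []
    if not matrices:
        logger.warning("filter_cohort received an empty cohort")
    for m in matrices:
        flags, fracs = [], []
        for d in range(m.n_days):
            frac = float(m.wear_mask[d].mean())
            fracs.append(frac)
            flags.append(is_valid_day(m.wear_mask[d], wear_fraction))
        report.wear_fraction[m.subject_id] = fracs
        report.valid_days[m.subject_id] = flags
        keep = [d for d, ok in enumerate(flags) if ok]
        if len(keep) < min_valid_days:
            report.excluded[m.subject_id] = (
                f"only {len(keep)} valid days (< {min_valid_days})"
            )
            continue
        kept = SubjectDayMatrix(
            subject_id=m.subject_id,
            days=[m.days[d] for d in keep],
            counts=m.counts[keep],
            wear_mask=m.wear_mask[keep],
            scale=m.scale,
            imputed=m.imputed[keep],
        )
        retained.append(kept)
    report.n_retained = len(retained)
    return retained, report


def preprocess_cohort(matrices, *, min_valid_days: int = MIN_VALID_DAYS,
                      wear_fraction: float = WEAR_FRACTION,
                      min_run: int = NONWEAR_MIN_RUN,
                      nonwear_policy: str = "exclude",
                      log_scale: bool = False):
    """Full fixed-order preprocessing of a raw cohort.

    Returns (clean matrices, QCReport).  Input matrices are not modified.
    """
    report = QCReport()
    staged = []
    for raw in matrices:
        m = raw.copy()
        # 1. DST fall: average duplicated minutes into the rectangular layout
        for day, rec in sorted(m.duplicate_hours.items()):
            base = m.counts[day].copy()
            merged = DayRecord(
                minutes=np.r_[np.flatnonzero(~np.isnan(base)), rec.minutes],
                values=np.r_[base[~np.isnan(base)], rec.values],
            )
            m.counts[day] = normalize_dst(merged, "fall")
            report.dst_adjusted.setdefault(m.subject_id, []).append(
                (str(m.days[day]), "fall"))
        m.duplicate_hours = {}
        # 2. DST spring / final hour / residual missing minutes
        for day in range(m.n_days):
            missing = np.isnan(m.counts[day])
            if missing.any():
                mode = "spring" if missing.sum() == 60 else "impute"
                _impute_missing(m, day)
                report.dst_adjusted.setdefault(m.subject_id, []).append(
                    (str(m.days[day]), mode))
        # 3. non-wear detection
        apply_nonwear(m, min_run=min_run, policy=nonwear_policy)
        staged.append(m)
    # 4-5. valid-day and subject filters
    retained, report = filter_cohort(staged, min_valid_days, wear_fraction, report)
    # 6. optional transform
    if log_scale:
        retained = [log_transform(m) for m in retained]
    return retained, report


# ---------------------------------------------------------------------------
# I/O: long CSV in, wide CSV + mask out
# ---------------------------------------------------------------------------

def read_long_csv(path) -> list:
    """Read the long minute-level CSV into raw SubjectDayMatrix objects.

    Columns: subject_id, date, minute_of_day, activity_count.  Absent rows
    become missing minutes (NaN); duplicated (date, minute) rows — a DST fall
    hour — are kept as duplicate records for later averaging.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "date", "minute_of_day", "activity_count"}
    if not required.issubset(df.columns):
        raise DimensionError(f"long CSV must have columns {sorted(required)}")
    out = []
    for sid, g in df.groupby("subject_id", sort=True):
        dates = sorted(g["date"].unique())
        counts = np.full((len(dates), MINUTES_PER_DAY), np.nan)
        dups = {}
        for d, (date, gd) in enumerate(
                g.sort_values(["date", "minute_of_day"]).groupby("date", sort=True)):
            minutes = gd["minute_of_day"].to_numpy(dtype=int)
            values = gd["activity_count"].to_numpy(dtype=float)
            first = ~pd.Series(minutes).duplicated().to_numpy()
            counts[d, minutes[first]] = values[first]
            if (~first).any():
                dups[d] = DayRecord(minutes[~first], values[~first])
        out.append(SubjectDayMatrix(subject_id=sid, days=dates, counts=counts,
                                    duplicate_hours=dups))
    return out


def write_wide_csv(matrices, counts_path, mask_path=None) -> None:
    """Cleaned matrices as wide CSV (row = subject-day) + sidecar wear mask."""
    rows, mrows = [], []
    cols = [f"m{t:04d}" for t in range(MINUTES_PER_DAY)]
    for m in matrices:
        for d in range(m.n_days):
            rows.append([m.subject_id, m.days[d], m.scale, *m.counts[d]])
            mrows.append([m.subject_id, m.days[d],
                          *m.wear_mask[d].astype(int)])
    head = ["subject_id", "date", "scale"]
    pd.DataFrame(rows, columns=head + cols).to_csv(
        counts_path, index=False, float_format="%.10g")
    if mask_path is not None:
        pd.DataFrame(mrows, columns=["subject_id", "date"] + cols).to_csv(
            mask_path, index=False)
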