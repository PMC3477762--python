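"""Reliability statistics: ICC(2,1) and Bland-Altman agreement.

Day-to-day and interrater reliability of the contact-stress metrics are
quantified with the Shrout-Fleiss single-score intraclass correlation for a
two-way random-effects, absolute-agreement design:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

where MSR, MSC and MSE are the rows (targets), columns (raters/days) and
residual mean squares of the two-way ANOVA over an n x k ratings matrix.
Bland-Altman summaries report the mean paired difference with limits of
agreement at exactly +/- 2 SD; pairs in which either measurement is zero
(no contact stress) are omitted and counted.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .geometry import ValidationError

logger = logging.getLogger(__name__)

METRICS = ("peak", "mean")
COMPARTMENTS = ("medial", "lateral")


class ICCUndefinedError(ValueError):
    """The ICC is undefined (zero total variance in the ratings matrix)."""


# ---------------------------------------------------------------------------
# ratings container
# ---------------------------------------------------------------------------

@dataclasses.dataclass(eq=False)
class RatingsTable:
    """knee x rater x day array of one contact-stress metric (MPa).

    ``mask`` flags missing cells (True = missing); designs in which some
    raters did not repeat on a second day are expressed through the mask.
    """

    values: np.ndarray
    metric: str = "peak"
    compartment: str = "medial"
    mask: np.ndarray | None = None
    knee_ids: list | None = None
    rater_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("ratings must be a knee x rater x day array")
        if self.values.shape[0] < 2:
            raise ValidationError("need at least 2 knees")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValidationError("mask shape must match values")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValidationError("unmasked ratings must be finite")
        if self.knee_ids is None:
            self.knee_ids = [f"knee{i:02d}" for i in range(self.values.shape[0])]
        if self.rater_ids is None:
            self.rater_ids = [f"rater{j}" for j in range(self.values.shape[1])]

    @property
    def n_knees(self) -> int:
        return self.values.shape[0]

    @property
    def k_raters(self) -> int:
        return self.values.shape[1]

    @property
    def n_days(self) -> int:
        return self.values.shape[2]

    # -- tidy CSV interchange (knee_id, rater_id, day, metric, compartment,
    #    value_mpa) --------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_knees):
            for j in range(self.k_raters):
                for d in range(self.n_days):
                    if self.mask[i, j, d]:
                        continue
                    rows.append(
                        {
                            "knee_id": self.knee_ids[i],
                            "rater_id": self.rater_ids[j],
                            "day": d + 1,
                            "metric": self.metric,
                            "compartment": self.compartment,
                            "value_mpa": self.values[i, j, d],
                        }
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metric: str, compartment: str) -> "RatingsTable":
        sub = df[(df["metric"] == metric) & (df["compartment"] == compartment)]
        if sub.empty:
            raise ValidationError(f"no rows for metric={metric}, compartment={compartment}")
        knees = sorted(sub["knee_id"].unique())
        raters = sorted(sub["rater_id"].unique())
        days = sorted(sub["day"].unique())
        values = np.full((len(knees), len(raters), len(days)), np.nan)
        for _, row in sub.iterrows():
            i = knees.index(row["knee_id"])
            j = raters.index(row["rater_id"])
            d = days.index(row["day"])
            values[i, j, d] = row["value_mpa"]
        mask = ~np.isfinite(values)
        values[mask] = 0.0
        return cls(
            values=values, metric=metric, compartment=compartment,
            mask=mask, knee_ids=knees, rater_ids=raters,
        )


def read_ratings_csv(path) -> list[RatingsTable]:
    """Read a tidy ratings CSV into one table per (metric, compartment)."""
    df = pd.read_csv(path)
    tables = []
    for metric in df["metric"].unique():
        for compartment in df[df["metric"] == metric]["compartment"].unique():
            tables.append(RatingsTable.from_frame(df, metric, compartment))
    return tables


def write_ratings_csv(tables: list[RatingsTable], path) -> None:
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ICCResult:
    """Single-score two-way random-effects ICC with its ANOVA mean squares."""

    icc: float
    msr: float  #: rows (targets) mean square
    msc: float  #: columns (raters/days) mean square
    mse: float  #: residual mean square
    n: int      #: targets retained
    k: int      #: columns
    n_dropped: int = 0  #: targets removed by listwise deletion


def icc_2_1(table: np.ndarray, mask: np.ndarray | None = None) -> ICCResult:
    """Shrout-Fleiss single-score ICC for absolute agreement, ICC(2,1).

    ``table`` is an n x k matrix (targets x columns, where columns are
    raters or days).  Rows containing masked or non-finite cells are
    dropped listwise with a logged count.  A matrix with zero total
    variance raises :class:`ICCUndefinedError` rather than returning a
    sentinel.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValidationError("ICC input must be a 2D targets x columns matrix")
    bad = ~np.isfinite(x)
    if mask is not None:
        bad |= np.asarray(mask, dtype=bool)
    keep = ~bad.any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("ICC: listwise-deleted %d target(s) with missing cells", n_dropped)
    x = x[keep]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError(f"ICC needs >= 2 targets and >= 2 columns, got {n} x {k}")

    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    if ss_total <= 1e-12 * max(1.0, grand**2):
        raise ICCUndefinedError("zero total variance: ICC undefined")

    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((col_means - grand) ** 2).sum()) / (k - 1)
    sse = float(
        ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    )
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return ICCResult(icc=float(icc), msr=msr, msc=msc, mse=mse, n=n, k=k, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class BlandAltmanSummary:
    mean_difference: float
    sd_difference: float
    upper_limit: float  #: mean + 2 SD exactly
    lower_limit: float  #: mean - 2 SD exactly
    points: np.ndarray  #: (n, 2) columns (pair mean, pair difference)
    n_omitted_zeros: int


def bland_altman(pairs, omit_zeros: bool = True) -> BlandAltmanSummary:
    """Agreement summary for paired measurements (a, b).

    Differences are a - b, plotted against the pair mean (a + b) / 2;
    limits of agreement are the mean difference +/- exactly 2 SD (sample
    SD).  Pairs in which either member is zero — no computed contact
    stress — are omitted and counted.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be an (n, 2) array")
    if omit_zeros:
        keep = (arr[:, 0] != 0) & (arr[:, 1] != 0)
    else:
        keep = np.ones(len(arr), dtype=bool)
    n_omitted = int((~keep).sum())
    arr = arr[keep]
    if len(arr) < 2:
        raise ValidationError(
            f"need >= 2 pairs after zero-omission, got {len(arr)}"
        )
    diff = arr[:, 0] - arr[:, 1]
    mean = arr.mean(axis=1)
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanSummary(
        mean_difference=md,
        sd_difference=sd,
        upper_limit=md + 2 * sd,
        lower_limit=md - 2 * sd,
        points=np.column_stack([mean, diff]),
        n_omitted_zeros=n_omitted,
    )


def day_to_day_pairs(table: RatingsTable) -> np.ndarray:
    """(day-1, day-2) pairs pooled over knees and raters with both days."""
    pairs = []
    for j in range(table.k_raters):
        ok = ~(table.mask[:, j, 0] | table.mask[:, j, 1]) if table.n_days >= 2 else None
        if table.n_days < 2:
            continue
        pairs.append(np.column_stack([table.values[ok, j, 0], table.values[ok, j, 1]]))
    if not pairs:
        raise ValidationError("no rater has two days of ratings")
    return np.vstack(pairs)


def interrater_pairs(table: RatingsTable, day: int = 0) -> np.ndarray:
    """All rater-pair combinations on one day, pooled over knees."""
    pairs = []
    for j1 in range(table.k_raters):
        for j2 in range(j1 + 1, table.k_raters):
            ok = ~(table.mask[:, j1, day] | table.mask[:, j2, day])
            pairs.append(
                np.column_stack([table.values[ok, j1, day], table.values[ok, j2, day]])
            )
    if not pairs:
        raise ValidationError("need at least 2 raters for interrater pairs")
    return np.vstack(pairs)


# ---------------------------------------------------------------------------
# study-level report
# ---------------------------------------------------------------------------

def _day_to_day_matrix(table: RatingsTable) -> tuple[np.ndarray, np.ndarray]:
    """Stack knee x rater combinations as rows; the 2 days as columns."""
    if table.n_days < 2:
        raise ValidationError("day-to-day reliability needs >= 2 days")
    vals = table.values[:, :, :2].reshape(-1, 2)
    mask = table.mask[:, :, :2].reshape(-1, 2)
    return vals, mask


def _interrater_matrix(table: RatingsTable) -> tuple[np.ndarray, np.ndarray]:
    """Knees as rows; raters as columns, using day-1 values."""
    return table.values[:, :, 0], table.mask[:, :, 0]


def reliability_report(tables: list[RatingsTable]) -> pd.DataFrame:
    """Per-metric day-to-day and interrater ICC(2,1) table.

    ``tables`` should cover the four metric/compartment combinations
    (peak/mean x medial/lateral).  The output has rows
    (day-to-day | interrater) x (medial | lateral) and columns
    (peak | mean); a missing design arm leaves an explicit NaN gap with a
    warning.

    Aggregation convention: day-to-day ICCs treat the 2 days as columns
    with knee x rater combinations stacked as targets; interrater ICCs
    treat raters as columns using day-1 values.
    """
    lookup = {(t.metric, t.compartment): t for t in tables}
    index = pd.MultiIndex.from_product(
        [["day-to-day", "interrater"], list(COMPARTMENTS)],
        names=["reliability", "compartment"],
    )
    report = pd.DataFrame(np.nan, index=index, columns=list(METRICS))
    for metric in METRICS:
        for compartment in COMPARTMENTS:
            table = lookup.get((metric, compartment))
            if table is None:
                warnings.warn(
                    f"missing ratings for ({metric}, {compartment}); gap left in report",
                    stacklevel=2,
                )
                continue
            for mode, builder in (
                ("day-to-day", _day_to_day_matrix),
                ("interrater", _interrater_matrix),
            ):
                try:
                    vals, mask = builder(table)
                    res = icc_2_1(vals, mask)
                    report.loc[(mode, compartment), metric] = res.icc
                except (ValidationError, ICCUndefinedError) as exc:
                    warnings.warn(
                        f"{mode} ICC unavailable for ({metric}, {compartment}): {exc}",
                        stacklevel=2,
                    )
    return report
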