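"""Surgeon-by-quarter quality-information states.

Patients choosing a cardiac surgeon can consult two streams of quality
information: crowd-sourced online reviews (1-5 stars, posted on dated
occasions) and state report cards that grade each surgeon's risk-adjusted
CABG mortality as lower than / as / greater than expected, published at
irregular dates.

This module collapses both streams into the information state a patient would
actually have seen at admission time:

* ``online_state`` in {high, low, none}: the running average of all stars
  posted strictly before the admission quarter, classified as *high* when it
  is at least four stars, *low* below four, and *none* when the surgeon has
  not yet been reviewed.
* ``report_state`` in {high, not_high, none}: *high* when the most recently
  published report card graded the surgeon lower-than-expected mortality;
  *not_high* for as-expected or greater-than-expected; *none* when the surgeon
  was unrated on that card or no card has been published yet.  A card is in
  effect from its publication quarter until the next card appears.

The strictly-before timing convention keeps the information set causal (a
review posted in the admission quarter may postdate the surgery); an inclusive
variant is available through ``include_same_quarter``.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Average star rating at or above which a surgeon counts as highly rated.
HIGH_RATING_THRESHOLD = 4.0

REPORT_CATEGORIES = ("lower_than_expected", "as_expected", "greater_than_expected")
ONLINE_STATES = ("high", "low", "none")
REPORT_STATES = ("high", "not_high", "none")

REVIEW_COLUMNS = ("surgeon_id", "post_date", "overall_stars")
PANEL_COLUMNS = ("surgeon_id", "quarter", "average_rating", "online_state", "report_state")


@dataclass(frozen=True)
class ReportCardIssue:
    """One published report card: a quarter of publication and the mapping
    from rated surgeons to their mortality category.  Surgeons below the
    issue's case-volume threshold are simply absent from ``scores``."""

    publication_date: int
    scores: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.scores.values() if c not in REPORT_CATEGORIES}
        if bad:
            raise ValueError(f"unknown report-card categories: {sorted(bad)}")


def average_rating_at(
    reviews: pd.DataFrame,
    surgeon_id: str,
    quarter: int,
    include_same_quarter: bool = False,
) -> float | None:
    """Running average star rating visible at admission in ``quarter``.

    The mean is taken over the surgeon's reviews posted strictly before the
    quarter (or through it, when ``include_same_quarter``).  Returns ``None``
    when no qualifying review exists, including for surgeons that never appear
    in the review stream.
    """
    sub = reviews[reviews["surgeon_id"] == surgeon_id]
    if sub.empty:
        logger.debug("surgeon %s has no reviews at all", surgeon_id)
        return None
    cutoff = quarter + 1 if include_same_quarter else quarter
    stars = sub.loc[sub["post_date"] < cutoff, "overall_stars"]
    if stars.empty:
        return None
    return float(stars.mean())


def classify_online(average: float | None) -> str:
    """Map a running average rating to the {high, low, none} state."""
    if average is None or (isinstance(average, float) and math.isnan(average)):
        return "none"
    if not 1.0 <= average <= 5.0:
        raise ValueError(f"average rating {average} outside the 1-5 star range")
    return "high" if average >= HIGH_RATING_THRESHOLD else "low"


def effective_report_card(
    issues: Sequence[ReportCardIssue], date: int
) -> ReportCardIssue | None:
    """The report card in effect at ``date``: the latest issue published at or
    before that quarter, or ``None`` before the first publication."""
    dates = [iss.publication_date for iss in issues]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("report-card issues must be sorted by unique publication date")
    k = bisect.bisect_right(dates, date) - 1
    return None if k < 0 else issues[k]


def classify_report(issue: ReportCardIssue | None, surgeon_id: str) -> str:
    """Map the effective issue (or its absence) to {high, not_high, none}."""
    if issue is None:
        return "none"
    category = issue.scores.get(surgeon_id)
    if category is None:
        return "none"
    return "high" if category == "lower_than_expected" else "not_high"


def build_quality_panel(
    reviews: pd.DataFrame,
    issues: Sequence[ReportCardIssue],
    surgeon_ids: Iterable[str],
    quarters: Iterable[int],
    include_same_quarter: bool = False,
) -> pd.DataFrame:
    """Full surgeon-by-quarter information panel.

    Returns a frame with one row per (surgeon_id, quarter) cell of the
    cartesian product, columns ``average_rating`` (NaN when unreviewed),
    ``online_state`` and ``report_state``.  States are surgeon-level: a
    surgeon practicing at several hospitals carries the same states at each.
    """
    sids = sorted(set(surgeon_ids))
    qs = np.asarray(sorted(set(int(q) for q in quarters)), dtype=np.int64)
    if len(sids) == 0 or len(qs) == 0:
        return pd.DataFrame(columns=list(PANEL_COLUMNS))
    if qs[0] < 0:
        raise ValueError("quarters must be non-negative")
    sindex = {s: i for i, s in enumerate(sids)}
    n_s, qmax = len(sids), int(qs[-1])

    counts = np.zeros((n_s, qmax + 1))
    sums = np.zeros((n_s, qmax + 1))
    if len(reviews):
        known = reviews[reviews["surgeon_id"].isin(sindex)]
        n_unknown = len(reviews) - len(known)
        if n_unknown:
            logger.warning("%d reviews reference surgeons outside the roster", n_unknown)
        post = known["post_date"].to_numpy(dtype=np.int64)
        if (post < 0).any():
            raise ValueError("review post_date must be non-negative")
        stars = known["overall_stars"].to_numpy(dtype=np.int64)
        if ((stars < 1) | (stars > 5)).any():
            raise ValueError("overall_stars must lie in 1..5")
        inwin = post <= qmax
        ridx = known["surgeon_id"].map(sindex).to_numpy(dtype=np.int64)[inwin]
        np.add.at(counts, (ridx, post[inwin]), 1.0)
        np.add.at(sums, (ridx, post[inwin]), stars[inwin].astype(float))
    ccount = counts.cumsum(axis=1)
    csum = sums.cumsum(axis=1)

    # Cumulative totals through the last quarter that counts for quarter q.
    cut = qs if include_same_quarter else qs - 1
    n_avail = np.where(cut[None, :] >= 0, ccount[:, np.clip(cut, 0, None)], 0.0)
    s_avail = np.where(cut[None, :] >= 0, csum[:, np.clip(cut, 0, None)], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(n_avail > 0, s_avail / n_avail, np.nan)
    online = np.where(
        n_avail == 0, "none", np.where(avg >= HIGH_RATING_THRESHOLD, "high", "low")
    )

    # Report state per surgeon per issue, then gathered per quarter.
    issues = list(issues)
    pub = [iss.publication_date for iss in issues]
    state_by_issue = np.full((n_s, len(issues)), "none", dtype=object)
    for j, iss in enumerate(issues):
        for sid, cat in iss.scores.items():
            i = sindex.get(sid)
            if i is not None:
                state_by_issue[i, j] = "high" if cat == "lower_than_expected" else "not_high"
    eff = np.searchsorted(pub, qs, side="right") - 1
    report = np.full((n_s, len(qs)), "none", dtype=object)
    for c, k in enumerate(eff):
        if k >= 0:
            report[:, c] = state_by_issue[:, k]

    panel = pd.DataFrame(
        {
            "surgeon_id": np.repeat(sids, len(qs)),
            "quarter": np.tile(qs, n_s),
            "average_rating": avg.ravel(),
            "online_state": online.ravel(),
            "report_state": report.ravel(),
        }
    )
    return panel


def reviewed_share(reviews: pd.DataFrame, surgeon_ids: Iterable[str]) -> float:
    """Fraction of roster surgeons with at least one review, whatever its date."""
    sids = set(surgeon_ids)
    if not sids:
        raise ValueError("empty surgeon roster")
    reviewed = set(reviews["surgeon_id"]) & sids
    return len(reviewed) / len(sids)


# ---------------------------------------------------------------------------
# CSV contract

def issues_to_frame(issues: Sequence[ReportCardIssue]) -> pd.DataFrame:
    rows = [
        (iss.publication_date, sid, cat)
        for iss in issues
        for sid, cat in sorted(iss.scores.items())
    ]
    return pd.DataFrame(rows, columns=["publication_date", "surgeon_id", "category"])


def issues_from_frame(frame: pd.DataFrame) -> list[ReportCardIssue]:
    issues = []
    for date, grp in frame.groupby("publication_date", sort=True):
        issues.append(
            ReportCardIssue(
                publication_date=int(date),
                scores=dict(zip(grp["surgeon_id"], grp["category"])),
            )
        )
    return issues


def read_reviews_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"surgeon_id": str})
    missing = set(REVIEW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reviews CSV missing columns: {sorted(missing)}")
    return df[list(REVIEW_COLUMNS)].astype(
        {"post_date": np.int64, "overall_stars": np.int64}
    )


def read_report_cards_csv(path) -> list[ReportCardIssue]:
    df = pd.read_csv(path, dtype={"surgeon_id": str})
    return issues_from_frame(df)


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False, float_format="%.17g")
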