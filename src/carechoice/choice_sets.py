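"""Geographic choice sets and the long-format estimation dataset.

Each CABG patient is modelled as choosing among surgeon-hospital pairs that
were geographically available at admission.  The baseline definition takes
every pair whose hospital lies within a fixed 50-mile radius of the patient's
residence, dropping patients whose realized choice was farther away.  A
robustness variant replaces the fixed circle by each hospital's empirical
market: the radius containing a configurable share (default 90%) of the
hospital's own realized patients.

The estimation contract is a long-format table with one row per
patient-alternative: quality-information indicators (high/no online rating,
high/no report card score), hospital attributes, the patient-hospital
distance in miles, the surgeon identity for fixed effects, and a single
``chosen`` row per patient.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Quality-information indicator block (the Q covariates).
QUALITY_ATTRS = ("high_online", "no_online", "high_report", "no_report")
#: Attributes whose coefficients are random by default (quality block + distance).
RANDOM_ATTRS = QUALITY_ATTRS + ("distance",)
#: Observed hospital attributes (the X covariates beyond distance).
HOSPITAL_ATTRS = ("bed_size", "teaching", "cicu")

LONG_COLUMNS = (
    "patient_id",
    "surgeon_id",
    "hospital_id",
    "quarter",
    "chosen",
    "distance",
    *QUALITY_ATTRS,
    *HOSPITAL_ATTRS,
    "emergency",
    "referral",
)

_EARTH_RADIUS_MILES = 3958.7613


@dataclass(frozen=True)
class Alternative:
    surgeon_id: str
    hospital_id: str
    bed_size: float
    teaching: int
    cicu: int
    distance_miles: float


@dataclass(frozen=True)
class ChoiceSet:
    patient_id: str
    quarter: int
    alternatives: tuple[Alternative, ...]
    chosen_index: int | None = None

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ValueError("choice set must be non-empty")
        pairs = [(a.surgeon_id, a.hospital_id) for a in self.alternatives]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate surgeon-hospital pairs in choice set")
        if self.chosen_index is not None and not (
            0 <= self.chosen_index < len(self.alternatives)
        ):
            raise ValueError("chosen_index out of range")


@dataclass
class ExclusionAudit:
    """Bookkeeping of sample restrictions: how many patients entered, how many
    survived, and how many were dropped for each reason."""

    n_patients: int = 0
    n_retained: int = 0
    reasons: dict = field(default_factory=dict)

    def add(self, reason: str, n: int = 1) -> None:
        self.reasons[reason] = self.reasons.get(reason, 0) + n

    @property
    def n_excluded(self) -> int:
        return sum(self.reasons.values())

    def excluded_pct(self) -> float:
        """Share of entering patients excluded, in percent."""
        return excluded_share_pct(self.n_excluded, self.n_patients)

    def to_json(self, path) -> None:
        payload = {
            "n_patients": self.n_patients,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "excluded_pct": self.excluded_pct() if self.n_patients else None,
            "reasons": dict(sorted(self.reasons.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def excluded_share_pct(n_excluded: int, n_total: int) -> float:
    """Percentage of a sample removed by a restriction (e.g. 1779 of 12,521
    discharges beyond the 50-mile cutoff -> 14.21)."""
    if n_total <= 0:
        raise ValueError("total count must be positive")
    if not 0 <= n_excluded <= n_total:
        raise ValueError("excluded count must lie in [0, total]")
    return 100.0 * n_excluded / n_total


# ---------------------------------------------------------------------------
# Distance

def distance_miles(a: Sequence[float], b: Sequence[float], mode: str = "planar") -> float:
    """Distance between two points in miles.

    ``mode='planar'`` treats inputs as (x, y) mile coordinates in the plane
    (the synthetic geography); ``mode='latlon'`` treats them as (latitude,
    longitude) degrees and returns the great-circle (haversine) distance.
    """
    ax, ay = float(a[0]), float(a[1])
    bx, by = float(b[0]), float(b[1])
    if not all(map(math.isfinite, (ax, ay, bx, by))):
        raise ValueError("coordinates must be finite")
    if mode == "planar":
        return math.hypot(ax - bx, ay - by)
    if mode == "latlon":
        return float(_haversine(np.array([ax]), np.array([ay]), np.array([bx]), np.array([by]))[0])
    raise ValueError(f"unknown distance mode {mode!r}")


def _haversine(lat1, lon1, lat2, lon2):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * _EARTH_RADIUS_MILES * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _distance_vec(px, py, hx, hy, mode: str):
    if mode == "planar":
        return np.hypot(px - hx, py - hy)
    if mode == "latlon":
        return _haversine(px, py, hx, hy)
    raise ValueError(f"unknown distance mode {mode!r}")


# ---------------------------------------------------------------------------
# Per-patient operations (the spec-level API; the pipeline uses the
# vectorized builder below, which applies the same rules)

def fixed_radius_choice_set(
    patient: Mapping,
    roster: pd.DataFrame,
    radius_miles: float = 50.0,
    distance_mode: str = "planar",
) -> tuple[ChoiceSet | None, str | None]:
    """Choice set of all roster pairs within ``radius_miles`` of the patient.

    Returns ``(choice_set, None)`` or ``(None, reason)`` when the patient is
    excluded: either the realized choice lies beyond the radius, or no pair is
    within reach.  ``roster`` needs columns surgeon_id, hospital_id, x, y and
    the hospital attributes.
    """
    if roster.empty:
        raise ValueError("roster must be non-empty")
    d = _distance_vec(
        float(patient["x"]), float(patient["y"]),
        roster["x"].to_numpy(float), roster["y"].to_numpy(float),
        distance_mode,
    )
    inside = d <= radius_miles
    chosen_pair = (patient.get("surgeon_id"), patient.get("hospital_id"))
    chosen_index = None
    if chosen_pair[0] is not None:
        match = (roster["surgeon_id"] == chosen_pair[0]) & (
            roster["hospital_id"] == chosen_pair[1]
        )
        if not match.any():
            return None, "chosen_not_in_roster"
        if not inside[match.to_numpy()].any():
            return None, "chosen_beyond_radius"
    if not inside.any():
        return None, "empty_choice_set"
    kept = roster.loc[inside].reset_index(drop=True)
    alts = tuple(
        Alternative(
            surgeon_id=r.surgeon_id,
            hospital_id=r.hospital_id,
            bed_size=float(r.bed_size),
            teaching=int(r.teaching),
            cicu=int(r.cicu),
            distance_miles=float(dd),
        )
        for r, dd in zip(kept.itertuples(), d[inside])
    )
    if chosen_pair[0] is not None:
        for i, a in enumerate(alts):
            if (a.surgeon_id, a.hospital_id) == chosen_pair:
                chosen_index = i
                break
    return (
        ChoiceSet(
            patient_id=str(patient["patient_id"]),
            quarter=int(patient["quarter"]),
            alternatives=alts,
            chosen_index=chosen_index,
        ),
        None,
    )


def hospital_market_radius(
    discharges: pd.DataFrame, hospital_id: str, coverage: float = 0.90
) -> float | None:
    """Radius of the hospital's empirical market: the ``coverage`` quantile
    (linear interpolation between order statistics) of realized
    patient-to-hospital distances.  ``None`` for hospitals with no discharges;
    such hospitals appear in no variable-radius choice set."""
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    d = discharges.loc[discharges["hospital_id"] == hospital_id, "distance"]
    if d.empty:
        return None
    return float(np.percentile(d.to_numpy(float), 100.0 * coverage, method="linear"))


def market_radii(discharges: pd.DataFrame, coverage: float = 0.90) -> pd.Series:
    """Market radius for every hospital with at least one discharge."""
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    return discharges.groupby("hospital_id")["distance"].quantile(
        coverage, interpolation="linear"
    )


def variable_radius_choice_set(
    patient: Mapping,
    roster: pd.DataFrame,
    radii: Mapping[str, float],
    distance_mode: str = "planar",
) -> tuple[ChoiceSet | None, str | None]:
    """Choice set of pairs whose hospital's own market covers the patient:
    pairs with patient-hospital distance <= that hospital's market radius."""
    if roster.empty:
        raise ValueError("roster must be non-empty")
    d = _distance_vec(
        float(patient["x"]), float(patient["y"]),
        roster["x"].to_numpy(float), roster["y"].to_numpy(float),
        distance_mode,
    )
    rad = roster["hospital_id"].map(radii).to_numpy(float)
    inside = np.isfinite(rad) & (d <= rad)
    chosen_pair = (patient.get("surgeon_id"), patient.get("hospital_id"))
    if chosen_pair[0] is not None:
        match = (
            (roster["surgeon_id"] == chosen_pair[0])
            & (roster["hospital_id"] == chosen_pair[1])
        ).to_numpy()
        if not match.any():
            return None, "chosen_not_in_roster"
        if not inside[match].any():
            return None, "chosen_outside_market"
    if not inside.any():
        return None, "empty_choice_set"
    kept = roster.loc[inside].reset_index(drop=True)
    alts = tuple(
        Alternative(
            surgeon_id=r.surgeon_id,
            hospital_id=r.hospital_id,
            bed_size=float(r.bed_size),
            teaching=int(r.teaching),
            cicu=int(r.cicu),
            distance_miles=float(dd),
        )
        for r, dd in zip(kept.itertuples(), d[inside])
    )
    chosen_index = None
    if chosen_pair[0] is not None:
        for i, a in enumerate(alts):
            if (a.surgeon_id, a.hospital_id) == chosen_pair:
                chosen_index = i
                break
    return (
        ChoiceSet(
            patient_id=str(patient["patient_id"]),
            quarter=int(patient["quarter"]),
            alternatives=alts,
            chosen_index=chosen_index,
        ),
        None,
    )


# ---------------------------------------------------------------------------
# Vectorized builder

def build_choice_rows(
    patients: pd.DataFrame,
    roster_for_quarter: Callable[[int], pd.DataFrame],
    radius: float | None = 50.0,
    radii: Mapping[str, float] | pd.Series | None = None,
    distance_mode: str = "planar",
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Cross every patient with the roster active in their admission quarter
    and apply the geographic availability rule.

    ``radius`` gives the fixed-radius rule (``None`` disables any radius);
    ``radii`` (mapping hospital_id -> miles) switches to the variable
    per-hospital market rule.  When ``patients`` carries realized
    surgeon_id/hospital_id columns, the returned rows include a ``chosen``
    flag and patients whose realized choice is unavailable are excluded and
    audited.
    """
    has_chosen = "surgeon_id" in patients.columns
    audit = ExclusionAudit(n_patients=len(patients))
    chunks: list[pd.DataFrame] = []
    for quarter, pgrp in patients.groupby("quarter", sort=True):
        roster = roster_for_quarter(int(quarter))
        np_, nr = len(pgrp), len(roster)
        if nr == 0:
            audit.add("empty_choice_set", np_)
            continue
        pidx = np.repeat(np.arange(np_), nr)
        ridx = np.tile(np.arange(nr), np_)
        d = _distance_vec(
            pgrp["x"].to_numpy(float)[pidx],
            pgrp["y"].to_numpy(float)[pidx],
            roster["x"].to_numpy(float)[ridx],
            roster["y"].to_numpy(float)[ridx],
            distance_mode,
        )
        if radii is not None:
            rad = roster["hospital_id"].map(radii).to_numpy(float)[ridx]
            inside = np.isfinite(rad) & (d <= rad)
        elif radius is not None:
            inside = d <= radius
        else:
            inside = np.ones_like(d, dtype=bool)
        chunk = pd.DataFrame(
            {
                "patient_id": pgrp["patient_id"].to_numpy()[pidx],
                "surgeon_id": roster["surgeon_id"].to_numpy()[ridx],
                "hospital_id": roster["hospital_id"].to_numpy()[ridx],
                "quarter": int(quarter),
                "distance": d,
            }
        )
        for col in HOSPITAL_ATTRS:
            chunk[col] = roster[col].to_numpy()[ridx]
        for col in ("emergency", "referral"):
            if col in pgrp.columns:
                chunk[col] = pgrp[col].to_numpy()[pidx]
        if has_chosen:
            chunk["chosen"] = (
                (chunk["surgeon_id"] == pgrp["surgeon_id"].to_numpy()[pidx])
                & (chunk["hospital_id"] == pgrp["hospital_id"].to_numpy()[pidx])
            ).astype(np.int64)
            per_pat_chosen = chunk.groupby("patient_id", sort=False)["chosen"].transform("max")
            chunk["_chosen_total"] = per_pat_chosen
        chunk["_inside"] = inside
        chunks.append(chunk)
    if not chunks:
        return pd.DataFrame(columns=list(LONG_COLUMNS)), audit
    rows = pd.concat(chunks, ignore_index=True)

    reason = "chosen_outside_market" if radii is not None else "chosen_beyond_radius"
    if has_chosen:
        not_in_roster = rows.loc[rows["_chosen_total"] == 0, "patient_id"].unique()
        if len(not_in_roster):
            audit.add("chosen_not_in_roster", len(not_in_roster))
            rows = rows[~rows["patient_id"].isin(not_in_roster)]
        chosen_inside = (
            rows.assign(_ci=(rows["chosen"] == 1) & rows["_inside"])
            .groupby("patient_id", sort=False)["_ci"]
            .transform("max")
        )
        beyond = rows.loc[~chosen_inside, "patient_id"].unique()
        if len(beyond):
            audit.add(reason, len(beyond))
            rows = rows[~rows["patient_id"].isin(beyond)]
    rows = rows[rows["_inside"]]
    # Empty sets can only remain in simulation mode (no chosen column).
    n_present = rows["patient_id"].nunique()
    n_entered = audit.n_patients - audit.n_excluded
    if n_present < n_entered:
        audit.add("empty_choice_set", n_entered - n_present)
    audit.n_retained = n_present
    rows = rows.drop(columns=[c for c in ("_inside", "_chosen_total") if c in rows.columns])
    rows = rows.sort_values(["patient_id", "surgeon_id", "hospital_id"], kind="stable")
    return rows.reset_index(drop=True), audit


def assemble_long_dataset(
    rows: pd.DataFrame,
    panel: pd.DataFrame,
    hospital_attrs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach quality-information indicators to patient-alternative rows.

    ``rows`` comes from :func:`build_choice_rows`; ``panel`` from
    :func:`carechoice.quality_linkage.build_quality_panel`.  Every
    (surgeon_id, quarter) referenced must have a panel cell (the panel is
    total by construction); a missing cell is a hard failure.
    """
    out = rows.copy()
    if hospital_attrs is not None and not set(HOSPITAL_ATTRS) <= set(out.columns):
        out = out.merge(
            hospital_attrs[["hospital_id", *HOSPITAL_ATTRS]], on="hospital_id", how="left"
        )
    merged = out.merge(
        panel[["surgeon_id", "quarter", "online_state", "report_state"]],
        on=["surgeon_id", "quarter"],
        how="left",
        validate="many_to_one",
    )
    if merged["online_state"].isna().any():
        bad = merged.loc[merged["online_state"].isna(), ["surgeon_id", "quarter"]]
        raise KeyError(
            "quality panel missing cells for "
            + ", ".join(f"({s}, {q})" for s, q in bad.drop_duplicates().head(5).itertuples(index=False))
        )
    merged["high_online"] = (merged["online_state"] == "high").astype(np.int64)
    merged["no_online"] = (merged["online_state"] == "none").astype(np.int64)
    merged["high_report"] = (merged["report_state"] == "high").astype(np.int64)
    merged["no_report"] = (merged["report_state"] == "none").astype(np.int64)
    merged = merged.drop(columns=["online_state", "report_state"])
    if "chosen" in merged.columns:
        per = merged.groupby("patient_id")["chosen"].sum()
        if (per != 1).any():
            raise ValueError("each patient must have exactly one chosen row")
    cols = [c for c in LONG_COLUMNS if c in merged.columns]
    cols += [c for c in merged.columns if c not in cols]
    values = merged[cols]
    if not np.isfinite(values.select_dtypes("number").to_numpy(float)).all():
        raise ValueError("non-finite covariates in assembled dataset")
    return values.reset_index(drop=True)


def apply_filters(
    dataset: pd.DataFrame,
    exclude_exited: bool = False,
    nonemergency_only: bool = False,
    nonreferral_only: bool = False,
    last_surgery: Mapping[str, int] | pd.Series | None = None,
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Robustness-sample restrictions on an assembled long dataset.

    The exited-surgeon rule removes *alternatives* (rows) for surgeons who
    performed no surgery in the patient's admission quarter nor afterwards
    (i.e. their last realized surgery predates the quarter); patients whose
    realized choice is removed are dropped entirely, as are patients left
    with an empty set.  Emergency/referral restrictions drop patients.
    """
    audit = ExclusionAudit(n_patients=dataset["patient_id"].nunique())
    out = dataset
    if nonemergency_only:
        if "emergency" not in out.columns:
            raise ValueError("dataset lacks the emergency flag")
        drop = out.loc[out["emergency"] == 1, "patient_id"].unique()
        audit.add("emergency_admission", len(drop))
        out = out[out["emergency"] == 0]
    if nonreferral_only:
        if "referral" not in out.columns:
            raise ValueError("dataset lacks the referral flag")
        drop = out.loc[out["referral"] == 1, "patient_id"].unique()
        audit.add("referral_admission", len(drop))
        out = out[out["referral"] == 0]
    if exclude_exited:
        if last_surgery is None:
            last_surgery = (
                dataset.loc[dataset["chosen"] == 1]
                .groupby("surgeon_id")["quarter"]
                .max()
            )
        last = out["surgeon_id"].map(last_surgery)
        exited = last.isna() | (last < out["quarter"])
        n_rows_dropped = int(exited.sum())
        lost_choice = out.loc[exited & (out["chosen"] == 1), "patient_id"].unique()
        out = out[~exited]
        if len(lost_choice):
            audit.add("chosen_surgeon_exited", len(lost_choice))
            out = out[~out["patient_id"].isin(lost_choice)]
        logger.info("attrition filter removed %d alternative rows", n_rows_dropped)
    before = set(dataset["patient_id"].unique())
    remaining = set(out["patient_id"].unique())
    emptied = len(before) - len(remaining) - audit.n_excluded
    if emptied > 0:
        audit.add("empty_after_filters", emptied)
    audit.n_retained = len(remaining)
    return out.reset_index(drop=True), audit


# ---------------------------------------------------------------------------
# CSV contract

def write_long_csv(dataset: pd.DataFrame, path) -> None:
    dataset.to_csv(path, index=False, float_format="%.17g")


def read_long_csv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "surgeon_id": str, "hospital_id": str},
        float_precision="round_trip",
    )
    missing = {"patient_id", "surgeon_id", "hospital_id", "quarter", "chosen", "distance"} - set(df.columns)
    if missing:
        raise ValueError(f"long CSV missing columns: {sorted(missing)}")
    return df
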