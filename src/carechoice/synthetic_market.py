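"""Synthetic surgical markets with known preference parameters.

The generator emulates the data landscape of the observational study this
package reproduces: ten years (40 quarters) of CABG discharges in a regional
market, a roster of surgeons affiliated with one or two hospitals, a stream
of dated 1-5 star online reviews skewed toward high values, and periodic
state report cards grading each sufficiently high-volume surgeon's
risk-adjusted mortality.  Patient choices are then drawn from the very
random-coefficient utility model the estimator targets, so that every
downstream stage can be tested against known truth:

    U_ijkt = Q_ijkt' beta_i + X_ijk' gamma + FE_k + eps_ijkt

with beta_i ~ N(mu, diag(sigma^2)) over the four quality indicators and
distance, fixed hospital-attribute coefficients gamma, surgeon fixed effects
FE, and i.i.d. type-1 extreme value shocks eps.

Geography is a square of configurable side with planar mile coordinates;
patient and hospital locations are snapped to a grid to mimic zip-code
granularity.  None of this aims at realistic US geography - only at
preserving the discretized-distance structure of the real data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import choice_sets, quality_linkage
from .choice_sets import HOSPITAL_ATTRS, RANDOM_ATTRS
from .quality_linkage import ReportCardIssue

logger = logging.getLogger(__name__)

#: Default star distribution over 1..5 stars, skewed high to emulate the
#: documented underrepresentation of low ratings on review platforms.
DEFAULT_STAR_DISTRIBUTION = (0.10, 0.05, 0.05, 0.20, 0.60)

#: Default report-card publication quarters: seven issues over a 40-quarter
#: window, roughly every 1.5 years.
DEFAULT_REPORT_QUARTERS = (2, 8, 13, 19, 24, 30, 35)


@dataclass(frozen=True)
class MarketConfig:
    """Generating conditions of a synthetic market.

    Defaults mirror the study population: 12,521 fee-for-service discharges
    by 184 surgeons over 40 quarters, with 1096/(184*40) ~= 0.149 expected
    reviews per surgeon-quarter and an emergency share of 31.52%.
    """

    n_patients: int = 12_521
    n_hospitals: int = 60
    n_surgeons: int = 184
    study_quarters: int = 40
    region_extent_miles: float = 200.0
    review_arrival_rate: float = 0.149
    star_distribution: tuple[float, ...] = DEFAULT_STAR_DISTRIBUTION
    report_card_quarters: tuple[int, ...] = DEFAULT_REPORT_QUARTERS
    emergency_share: float = 0.3152
    referral_share: float = 0.30
    attrition_share: float = 0.15
    grid_miles: float = 5.0
    teaching_share: float = 0.5
    cicu_share: float = 0.9
    second_affiliation_prob: float = 0.35
    min_cases_for_score: int = 30
    report_window_quarters: int = 8
    report_low_pct: float = 0.10
    report_high_pct: float = 0.90
    score_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_hospitals", "n_surgeons", "study_quarters"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("region_extent_miles", "grid_miles"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        if not (math.isfinite(self.review_arrival_rate) and self.review_arrival_rate >= 0):
            raise ValueError(
                f"review_arrival_rate must be non-negative, got {self.review_arrival_rate!r}"
            )
        sd = np.asarray(self.star_distribution, dtype=float)
        if sd.shape != (5,) or (sd < 0).any() or not math.isclose(sd.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("star_distribution must be 5 non-negative probabilities summing to 1")
        rq = list(self.report_card_quarters)
        if any(b <= a for a, b in zip(rq, rq[1:])):
            raise ValueError("report_card_quarters must be strictly increasing")
        if rq and (rq[0] < 0 or rq[-1] >= self.study_quarters):
            raise ValueError("report_card_quarters must lie within the study window")
        for name in ("emergency_share", "referral_share", "attrition_share",
                     "teaching_share", "cicu_share",
                     "second_affiliation_prob", "report_low_pct", "report_high_pct"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.report_low_pct >= self.report_high_pct:
            raise ValueError("report_low_pct must be below report_high_pct")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["star_distribution"] = list(self.star_distribution)
        d["report_card_quarters"] = list(self.report_card_quarters)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "MarketConfig":
        d = dict(d)
        if "star_distribution" in d:
            d["star_distribution"] = tuple(d["star_distribution"])
        if "report_card_quarters" in d:
            d["report_card_quarters"] = tuple(d["report_card_quarters"])
        return cls(**d)


@dataclass(frozen=True)
class TrueParameters:
    """Generating coefficients of a synthetic market.

    ``mu``/``sigma`` give the mean and SD of the normal random coefficients
    on the quality indicators and distance; ``gamma`` the fixed coefficients
    on hospital attributes; ``fe`` the surgeon fixed effects with one
    reference surgeon pinned to exactly 0.
    """

    mu: Mapping[str, float]
    sigma: Mapping[str, float]
    gamma: Mapping[str, float]
    fe: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(RANDOM_ATTRS) - set(self.mu)
        if missing:
            raise ValueError(f"mu missing attributes: {sorted(missing)}")
        missing = set(RANDOM_ATTRS) - set(self.sigma)
        if missing:
            raise ValueError(f"sigma missing attributes: {sorted(missing)}")
        if any(s < 0 for s in self.sigma.values()):
            raise ValueError("sigma values must be non-negative")
        if self.fe and not any(v == 0.0 for v in self.fe.values()):
            raise ValueError("one surgeon fixed effect must be pinned to 0")

    def to_dict(self) -> dict:
        return {
            "mu": dict(self.mu),
            "sigma": dict(self.sigma),
            "gamma": dict(self.gamma),
            "fe": dict(self.fe),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrueParameters":
        return cls(mu=dict(d["mu"]), sigma=dict(d["sigma"]),
                   gamma=dict(d["gamma"]), fe=dict(d["fe"]))


@dataclass
class SyntheticStudy:
    """A complete synthetic study: geography, rosters, information streams,
    and (after choice simulation) realized discharges with known truth."""

    config: MarketConfig
    patients: pd.DataFrame
    hospitals: pd.DataFrame
    surgeons: pd.DataFrame
    reviews: pd.DataFrame
    report_cards: list[ReportCardIssue]
    truth: TrueParameters | None = None
    discharges: pd.DataFrame | None = None
    n_excluded_empty: int = 0

    @property
    def quarters(self) -> range:
        return range(self.config.study_quarters)

    def pair_roster(self) -> pd.DataFrame:
        """All surgeon-hospital pairs with hospital attributes and coordinates."""
        rows = []
        hosp = self.hospitals.set_index("hospital_id")
        for s in self.surgeons.itertuples():
            for hid in s.hospital_ids.split("|"):
                h = hosp.loc[hid]
                rows.append(
                    (s.surgeon_id, hid, h["x"], h["y"], h["bed_size"], h["teaching"], h["cicu"],
                     s.exit_quarter)
                )
        return pd.DataFrame(
            rows,
            columns=["surgeon_id", "hospital_id", "x", "y", *HOSPITAL_ATTRS, "exit_quarter"],
        )

    def roster_at(self, quarter: int) -> pd.DataFrame:
        """Active pairs at ``quarter``: surgeons who have not yet exited."""
        roster = self.pair_roster()
        return roster[roster["exit_quarter"] > quarter].reset_index(drop=True)


def default_true_parameters(
    surgeon_ids: Sequence[str], seed: int = 0, fe_sd: float = 0.5
) -> TrueParameters:
    """Generating parameters at the magnitudes of the study's main estimates:
    means and SDs of the quality and distance coefficients taken from the
    fitted model of the real market, invented fixed hospital-attribute
    coefficients of plausible size, and N(0, fe_sd^2) surgeon fixed effects
    with the first (sorted) surgeon as the zero reference."""
    rng = np.random.default_rng(seed)
    sids = sorted(surgeon_ids)
    fe = {sid: float(v) for sid, v in zip(sids, rng.normal(0.0, fe_sd, size=len(sids)))}
    fe[sids[0]] = 0.0
    return TrueParameters(
        mu={
            "high_online": 0.317,
            "no_online": 0.536,
            "high_report": -0.057,
            "no_report": -0.516,
            "distance": -0.278,
        },
        sigma={
            "high_online": 0.0643,
            "no_online": 1.015,
            "high_report": 0.326,
            "no_report": 0.828,
            "distance": 0.122,
        },
        gamma={"bed_size": 0.0005, "teaching": 0.15, "cicu": 0.40},
        fe=fe,
    )


def _snap(x: np.ndarray, grid: float) -> np.ndarray:
    return np.round(x / grid) * grid


def generate_market(config: MarketConfig) -> SyntheticStudy:
    """Generate geography, providers and information streams (no choices yet).

    Deterministic given ``config.seed``: two calls with the same config are
    byte-identical.  Patient choices are added by :func:`simulate_choices`.
    """
    rng = np.random.default_rng(config.seed)
    L, grid, Q = config.region_extent_miles, config.grid_miles, config.study_quarters

    hids = [f"H{i:03d}" for i in range(config.n_hospitals)]
    hospitals = pd.DataFrame(
        {
            "hospital_id": hids,
            "x": _snap(rng.uniform(0, L, config.n_hospitals), grid),
            "y": _snap(rng.uniform(0, L, config.n_hospitals), grid),
            "bed_size": np.round(np.exp(rng.normal(np.log(400.0), 0.5, config.n_hospitals))),
            "teaching": (rng.random(config.n_hospitals) < config.teaching_share).astype(np.int64),
            "cicu": (rng.random(config.n_hospitals) < config.cicu_share).astype(np.int64),
        }
    )

    sids = [f"S{i:03d}" for i in range(config.n_surgeons)]
    primary = rng.integers(0, config.n_hospitals, config.n_surgeons)
    second = rng.integers(0, config.n_hospitals, config.n_surgeons)
    has_second = (rng.random(config.n_surgeons) < config.second_affiliation_prob) & (
        second != primary
    )
    affil = [
        "|".join(sorted({hids[p]} | ({hids[s]} if hs else set())))
        for p, s, hs in zip(primary, second, has_second)
    ]
    exits = np.full(config.n_surgeons, Q, dtype=np.int64)
    attriting = rng.random(config.n_surgeons) < config.attrition_share
    exits[attriting] = rng.integers(Q // 2, Q, attriting.sum())
    surgeons = pd.DataFrame(
        {
            "surgeon_id": sids,
            "hospital_ids": affil,
            "latent_mortality": rng.normal(0.0, 1.0, config.n_surgeons),
            "latent_volume": np.exp(rng.normal(np.log(6.0), 0.6, config.n_surgeons)),
            "exit_quarter": exits,
        }
    )

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(config.n_patients)],
            "x": _snap(rng.uniform(0, L, config.n_patients), grid),
            "y": _snap(rng.uniform(0, L, config.n_patients), grid),
            "quarter": rng.integers(0, Q, config.n_patients),
            "emergency": (rng.random(config.n_patients) < config.emergency_share).astype(np.int64),
            "referral": (rng.random(config.n_patients) < config.referral_share).astype(np.int64),
        }
    )

    # Review stream: per surgeon-quarter Poisson arrivals, i.i.d. stars.
    arrivals = rng.poisson(config.review_arrival_rate, size=(config.n_surgeons, Q))
    stars_cdf = np.cumsum(config.star_distribution)
    rev_s, rev_q, rev_stars = [], [], []
    for i, sid in enumerate(sids):
        for q in range(Q):
            n = int(arrivals[i, q])
            if n:
                u = rng.random(n)
                st = 1 + np.searchsorted(stars_cdf, u, side="right")
                rev_s.extend([sid] * n)
                rev_q.extend([q] * n)
                rev_stars.extend(np.clip(st, 1, 5).tolist())
    reviews = pd.DataFrame(
        {
            "surgeon_id": rev_s,
            "post_date": np.asarray(rev_q, dtype=np.int64),
            "overall_stars": np.asarray(rev_stars, dtype=np.int64),
        }
    )

    # Report cards: surgeons above a case-volume threshold in the issue's
    # collection window get a category from their (noisy) latent mortality
    # percentile; the rest are unrated.
    issues: list[ReportCardIssue] = []
    vol = surgeons["latent_volume"].to_numpy()
    mort = surgeons["latent_mortality"].to_numpy()
    for pub_q in config.report_card_quarters:
        window = min(config.report_window_quarters, max(pub_q, 1))
        cases = rng.poisson(vol * window)
        active = exits > pub_q  # exited surgeons drop off subsequent cards
        rated = (cases >= config.min_cases_for_score) & active
        scores: dict[str, str] = {}
        if rated.any():
            noisy = mort[rated] + rng.normal(0.0, config.score_noise_sd, rated.sum())
            ranks = noisy.argsort().argsort() / max(rated.sum() - 1, 1)
            cats = np.where(
                ranks < config.report_low_pct,
                "lower_than_expected",
                np.where(ranks > config.report_high_pct, "greater_than_expected", "as_expected"),
            )
            scores = {str(s): str(c) for s, c in zip(np.asarray(sids)[rated], cats)}
        issues.append(ReportCardIssue(publication_date=int(pub_q), scores=scores))

    return SyntheticStudy(
        config=config,
        patients=patients,
        hospitals=hospitals,
        surgeons=surgeons,
        reviews=reviews,
        report_cards=issues,
    )


def simulate_choices(
    study: SyntheticStudy, truth: TrueParameters, seed: int
) -> SyntheticStudy:
    """Draw each patient's choice from the random-coefficient utility model.

    Per patient: coefficients beta_i ~ N(mu, diag(sigma^2)), one independent
    type-1 extreme value shock per alternative (inverse-CDF transform
    -log(-log U) of uniforms from the seeded generator), utilities over the
    full roster of pairs active in the admission quarter, and the argmax
    recorded as the chosen surgeon-hospital pair.  Patients with an empty
    choice set (all surgeons exited) are excluded with a logged count.
    """
    cfg = study.config
    panel = quality_linkage.build_quality_panel(
        study.reviews,
        study.report_cards,
        study.surgeons["surgeon_id"],
        range(cfg.study_quarters),
    )
    rows, audit = choice_sets.build_choice_rows(
        study.patients, study.roster_at, radius=None
    )
    n_empty = audit.reasons.get("empty_choice_set", 0)
    if n_empty:
        logger.warning("%d patients excluded for empty choice sets", n_empty)
    data = choice_sets.assemble_long_dataset(rows, panel)

    missing_fe = set(data["surgeon_id"].unique()) - set(truth.fe)
    if missing_fe:
        raise ValueError(f"truth.fe missing surgeons: {sorted(missing_fe)[:5]}")

    rng = np.random.default_rng(seed)
    pid_codes, pid_uniques = pd.factorize(data["patient_id"], sort=True)
    n_pat = len(pid_uniques)
    mu = np.array([truth.mu[a] for a in RANDOM_ATTRS])
    sg = np.array([truth.sigma[a] for a in RANDOM_ATTRS])
    beta = mu + sg * rng.standard_normal((n_pat, len(RANDOM_ATTRS)))

    X_rand = data[list(RANDOM_ATTRS)].to_numpy(float)
    X_fix = data[list(HOSPITAL_ATTRS)].to_numpy(float)
    gamma = np.array([truth.gamma.get(a, 0.0) for a in HOSPITAL_ATTRS])
    fe = data["surgeon_id"].map(truth.fe).to_numpy(float)
    eps = -np.log(-np.log(rng.random(len(data))))
    util = (X_rand * beta[pid_codes]).sum(axis=1) + X_fix @ gamma + fe + eps

    data = data.assign(_util=util)
    chosen_idx = data.groupby("patient_id", sort=True)["_util"].idxmax()
    chosen = data.loc[chosen_idx]
    discharges = chosen[
        ["patient_id", "quarter", "surgeon_id", "hospital_id", "distance"]
    ].copy()
    discharges = discharges.merge(
        study.patients[["patient_id", "x", "y", "emergency", "referral"]],
        on="patient_id",
    )
    discharges = discharges.sort_values("patient_id").reset_index(drop=True)
    return dataclasses.replace(
        study, truth=truth, discharges=discharges, n_excluded_empty=n_empty
    )


# ---------------------------------------------------------------------------
# Disk round-trip (long CSVs + JSON sidecar)

_FLOAT_FMT = "%.17g"


def save_study(study: SyntheticStudy, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.patients.to_csv(out / "patients.csv", index=False, float_format=_FLOAT_FMT)
    study.hospitals.to_csv(out / "hospitals.csv", index=False, float_format=_FLOAT_FMT)
    study.surgeons.to_csv(out / "surgeons.csv", index=False, float_format=_FLOAT_FMT)
    study.reviews.to_csv(out / "reviews.csv", index=False, float_format=_FLOAT_FMT)
    quality_linkage.issues_to_frame(study.report_cards).to_csv(
        out / "report_cards.csv", index=False
    )
    if study.discharges is not None:
        study.discharges.to_csv(out / "discharges.csv", index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "config": study.config.to_dict(),
        "truth": study.truth.to_dict() if study.truth else None,
        "n_excluded_empty": study.n_excluded_empty,
        # Issues with no rated surgeon have no CSV rows; keep their dates.
        "report_card_dates": [i.publication_date for i in study.report_cards],
    }
    with open(out / "study.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def _issues_with_dates(
    issues: list[ReportCardIssue], dates: Sequence[int] | None
) -> list[ReportCardIssue]:
    if dates is None:
        return issues
    by_date = {i.publication_date: i for i in issues}
    return [
        by_date.get(int(d), ReportCardIssue(publication_date=int(d), scores={}))
        for d in sorted(dates)
    ]


def load_study(outdir) -> SyntheticStudy:
    out = Path(outdir)
    with open(out / "study.json") as fh:
        sidecar = json.load(fh)
    discharges = None
    if (out / "discharges.csv").exists():
        discharges = pd.read_csv(
            out / "discharges.csv",
            dtype={"patient_id": str, "surgeon_id": str, "hospital_id": str},
            float_precision="round_trip",
        ).astype({"distance": float, "x": float, "y": float})
    return SyntheticStudy(
        config=MarketConfig.from_dict(sidecar["config"]),
        patients=pd.read_csv(
            out / "patients.csv", dtype={"patient_id": str},
            float_precision="round_trip",
        ).astype({"x": float, "y": float}),
        hospitals=pd.read_csv(
            out / "hospitals.csv", dtype={"hospital_id": str},
            float_precision="round_trip",
        ).astype({"x": float, "y": float, "bed_size": float}),
        surgeons=pd.read_csv(
            out / "surgeons.csv", dtype={"surgeon_id": str, "hospital_ids": str},
            float_precision="round_trip",
        ),
        reviews=pd.read_csv(out / "reviews.csv", dtype={"surgeon_id": str}),
        report_cards=_issues_with_dates(
            quality_linkage.read_report_cards_csv(out / "report_cards.csv"),
            sidecar.get("report_card_dates"),
        ),
        truth=TrueParameters.from_dict(sidecar["truth"]) if sidecar["truth"] else None,
        discharges=discharges,
        n_excluded_empty=sidecar.get("n_excluded_empty", 0),
    )
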