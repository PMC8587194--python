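"""Derived statistics from a fitted random-coefficient logit.

* heterogeneity shares: the mass Phi(mu/sigma) of a normal coefficient
  distribution lying above zero (e.g. the share of patients who prefer an
  unreviewed surgeon to a low-rated one);
* willingness to travel: -mu_attribute / mu_distance, in miles;
* baseline choice probability: the mean over patients of 1/|choice set|;
* bootstrap average marginal effects: the change in a randomly selected
  surgeon's predicted choice probability when a quality indicator toggles
  from 0 to 1, averaged over patients and bootstrap replicates;
* year-by-year marginal utilities from attribute-by-trend interaction fits,
  with delta-method confidence intervals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .mixed_logit import DrawSet, EstimationData, FitResult, make_draws
from .quarters import year_trend

logger = logging.getLogger(__name__)

#: Each quality indicator's mutually exclusive "no information" companion.
COMPANION = {
    "high_online": "no_online",
    "no_online": "high_online",
    "high_report": "no_report",
    "no_report": "high_report",
}


class SharePreferring(NamedTuple):
    share: float
    complement: float
    degenerate: bool = False


def share_preferring(mean: float, sd: float) -> SharePreferring:
    """Share of the N(mean, sd^2) coefficient distribution above zero.

    This is the cumulative-normal heterogeneity statistic Phi(mean/sd): the
    fraction of patients whose individual coefficient is positive.  The
    complement is returned alongside.  ``sd == 0`` is a degenerate
    distribution (share 0 or 1, flagged); negative sd is rejected.
    """
    if not np.isfinite(mean) or not np.isfinite(sd):
        raise ValueError("mean and sd must be finite")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        share = 1.0 if mean > 0 else (0.5 if mean == 0 else 0.0)
        return SharePreferring(share, 1.0 - share, degenerate=True)
    share = float(norm.cdf(mean / sd))
    return SharePreferring(share, 1.0 - share, degenerate=False)


class WttResult(NamedTuple):
    miles: float
    se: float | None


def willingness_to_travel(
    fit: FitResult, attribute: str, distance_attr: str = "distance",
    with_se: bool = True,
) -> WttResult:
    """Willingness to travel for the attribute, in miles.

    The negative ratio of the attribute's mean coefficient to the distance
    mean coefficient: the extra miles a patient would accept to obtain the
    attribute.  Delta-method SE from the fit's covariance when available.
    """
    a = fit.mu(attribute)
    d = fit.mu(distance_attr)
    if d == 0:
        raise ValueError("distance mean coefficient is zero; WTT undefined")
    wtt = -a / d
    se = None
    if with_se:
        ka, kd = f"mu:{attribute}", f"mu:{distance_attr}"
        v = fit.vcov
        if np.isfinite(v.loc[ka, ka]):
            grad = np.array([-1.0 / d, a / d**2])
            sub = v.loc[[ka, kd], [ka, kd]].to_numpy()
            se = float(np.sqrt(grad @ sub @ grad))
    return WttResult(wtt, se)


def baseline_choice_probability(data: EstimationData | pd.DataFrame) -> float:
    """Average over patients of 1/|choice set|: the probability of any one
    surgeon being chosen when choices were uniform."""
    if isinstance(data, EstimationData):
        sizes = data.sizes
    else:
        if len(data) == 0:
            raise ValueError("empty dataset")
        sizes = data.groupby("patient_id").size().to_numpy()
    return float((1.0 / sizes).mean())


@dataclass
class AmeResult:
    """Bootstrap average marginal effect of a quality indicator.

    ``ame_pp`` is in percentage points (mean over replicates of the average
    probability change); ``relative`` is the probability-scale AME divided by
    the baseline choice probability."""

    attribute: str
    ame_pp: float
    baseline: float
    relative: float
    ci_low_pp: float
    ci_high_pp: float
    n_boot: int
    seed: int
    n_draws: int
    integrate: bool

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "ame_pp": self.ame_pp,
            "baseline": self.baseline,
            "relative": self.relative,
            "ci_low_pp": self.ci_low_pp,
            "ci_high_pp": self.ci_high_pp,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_draws": self.n_draws,
            "integrate": self.integrate,
        }


def _row_toggle_diffs(
    fit: FitResult,
    data: EstimationData,
    attribute: str,
    draws: DrawSet,
    chunk: int = 256,
) -> np.ndarray:
    """Per-row predicted-probability change when ``attribute`` toggles 1 vs 0
    for that alternative (its exclusive "none" companion forced to 0 in both
    arms), integrating the conditional logit over the fitted mixing density.
    """
    spec = data.spec
    ka = spec.random_attrs.index(attribute)
    comp = COMPANION[attribute]
    kc = spec.random_attrs.index(comp) if comp in spec.random_attrs else None
    K = data.n_rand
    theta = fit.params
    mu = np.array([theta[f"mu:{a}"] for a in spec.random_attrs])
    sg = np.array([theta[f"sd:{a}"] for a in spec.random_attrs])
    gam = np.array([theta[nm] for nm in data.fixed_names]) if data.n_fixed else None

    base = data.X_rand @ mu
    if gam is not None:
        base = base + data.X_fixed @ gam

    # Fixed interaction terms shift the effective toggle coefficient by
    # theta_ix * trend for the patient's admission year.
    trend_shift_a = np.zeros(data.n_patients)
    trend_shift_c = np.zeros(data.n_patients)
    t = year_trend(data.patient_quarter, spec.trend_origin).astype(float)
    if f"ix:{attribute}" in data.fixed_names:
        trend_shift_a = theta[f"ix:{attribute}"] * t
    if kc is not None and f"ix:{comp}" in data.fixed_names:
        trend_shift_c = theta[f"ix:{comp}"] * t

    xa = data.X_rand[:, ka]
    xc = data.X_rand[:, kc] if kc is not None else np.zeros(data.n_rows)
    rep = data.rep
    acc = np.zeros(data.n_rows)
    R = draws.n_draws
    for lo in range(0, R, chunk):
        hi = min(lo + chunk, R)
        zc = draws.z[:, lo:hi, :]
        C = hi - lo
        U = np.repeat(base[:, None], C, axis=1)
        for k in range(K):
            if sg[k] != 0.0:
                U += sg[k] * (data.X_rand[:, k, None] * zc[rep, :, k])
        m = np.maximum.reduceat(U, data.starts, axis=0)
        np.subtract(U, m[rep], out=U)
        np.exp(U, out=U)
        denom = np.add.reduceat(U, data.starts, axis=0)

        b_a = mu[ka] + sg[ka] * zc[:, :, ka] + trend_shift_a[:, None]  # (P, C)
        b_c = (
            mu[kc] + sg[kc] * zc[:, :, kc] + trend_shift_c[:, None]
            if kc is not None
            else np.zeros((data.n_patients, C))
        )
        d1 = b_a[rep] * (1.0 - xa[:, None]) - b_c[rep] * xc[:, None]
        d0 = -b_a[rep] * xa[:, None] - b_c[rep] * xc[:, None]
        e1 = U * np.exp(d1)
        e0 = U * np.exp(d0)
        p1 = e1 / (denom[rep] - U + e1)
        p0 = e0 / (denom[rep] - U + e0)
        acc += (p1 - p0).sum(axis=1)
    return acc / R


def ame_bootstrap(
    fit: FitResult,
    data: EstimationData | pd.DataFrame,
    attribute: str,
    n_boot: int = 1000,
    seed: int = 0,
    n_draws: int = 1000,
    integrate: bool = True,
) -> AmeResult:
    """Bootstrap AME of a quality indicator on the probability of being chosen.

    Each replicate picks one alternative uniformly from every patient's
    choice set and averages, over patients, the change in that alternative's
    predicted probability when the indicator is set to 1 (companion "none"
    dummy forced to 0) versus 0.  Predicted probabilities integrate over the
    fitted mixing distribution with a fresh Halton draw set
    (``integrate=False`` evaluates at the mean coefficients instead).
    Deterministic given ``seed``.
    """
    if isinstance(data, pd.DataFrame):
        data = EstimationData(data, fit.spec)
    if attribute not in COMPANION:
        raise ValueError(f"{attribute!r} is not a quality indicator")
    if attribute not in data.spec.random_attrs:
        raise ValueError(f"{attribute!r} is not in the model's random attributes")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if integrate:
        ds = make_draws(data.n_patients, data.n_rand, n_draws, method="halton")
    else:
        ds = DrawSet(
            method="degenerate",
            n_draws=1,
            seed=seed,
            z=np.zeros((data.n_patients, 1, data.n_rand)),
        )
    diffs = _row_toggle_diffs(fit, data, attribute, ds)

    rng = np.random.default_rng(seed)
    offsets = (rng.random((n_boot, data.n_patients)) * data.sizes).astype(np.int64)
    picks = data.starts[None, :] + offsets
    boot = diffs[picks].mean(axis=1)  # (n_boot,)
    ame_prob = float(boot.mean())
    lo, hi = np.percentile(boot, [2.5, 97.5])
    baseline = baseline_choice_probability(data)
    return AmeResult(
        attribute=attribute,
        ame_pp=100.0 * ame_prob,
        baseline=baseline,
        relative=ame_prob / baseline,
        ci_low_pp=100.0 * float(lo),
        ci_high_pp=100.0 * float(hi),
        n_boot=n_boot,
        seed=seed,
        n_draws=ds.n_draws,
        integrate=integrate,
    )


def year_effects(
    fit: FitResult,
    attribute: str,
    years: Sequence[int],
    origin_year: int = 2008,
) -> pd.DataFrame:
    """Yearly marginal utility of an attribute from an interaction fit.

    For year y with trend value t = y - origin_year the marginal utility is
    mu_main + theta_interaction * t; its SE follows from the delta method on
    the (main, interaction) covariance block, with 95% CI = estimate +/-
    1.96 SE.
    """
    km, ki = f"mu:{attribute}", f"ix:{attribute}"
    if ki not in fit.params.index:
        raise ValueError(f"fit has no interaction term for {attribute!r}")
    main = float(fit.params[km])
    inter = float(fit.params[ki])
    vmm = float(fit.vcov.loc[km, km])
    vii = float(fit.vcov.loc[ki, ki])
    vmi = float(fit.vcov.loc[km, ki])
    rows = []
    for y in years:
        t = float(y - origin_year)
        eff = main + inter * t
        var = vmm + t * t * vii + 2.0 * t * vmi
        se = float(np.sqrt(max(var, 0.0)))
        rows.append((int(y), t, eff, se, eff - 1.96 * se, eff + 1.96 * se))
    return pd.DataFrame(
        rows, columns=["year", "trend", "effect", "se", "ci_low", "ci_high"]
    )


def write_post_report(path, shares: dict, wtt: dict, ames: list[AmeResult], baseline: float) -> None:
    payload = {
        "shares_above_zero": shares,
        "willingness_to_travel_miles": wtt,
        "baseline_choice_probability": baseline,
        "average_marginal_effects": [a.to_dict() for a in ames],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
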