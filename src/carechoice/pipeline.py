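"""End-to-end orchestration: simulate -> link -> build -> fit -> post -> robustness.

A single declarative YAML config drives a full reproducible run.  Every
artifact is a CSV or JSON file regenerable from (config, seed) alone; the
config is echoed into the output directory so a run documents itself.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import choice_sets, postestimation, quality_linkage, synthetic_market
from .choice_sets import QUALITY_ATTRS
from .mixed_logit import EstimationData, ModelSpec, fit as fit_mixed
from .synthetic_market import MarketConfig, SyntheticStudy

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "link", "build", "fit", "post", "robustness", "interactions")

#: Binary columns reported as percentages (x100) in descriptive tables.
_PERCENT_COLS = ("emergency", "referral", *QUALITY_ATTRS, "teaching", "cicu")


@dataclass
class RunConfig:
    market: MarketConfig = field(default_factory=MarketConfig)
    radius_mode: str = "fixed_50"  # fixed_50 | variable_90 | custom
    radius_miles: float = 50.0
    coverage: float = 0.90
    filters: dict = field(default_factory=dict)
    draws: int = 1000
    draw_method: str = "halton"
    seed: int = 0
    tol: float = 1e-4
    max_iter: int = 200
    n_boot: int = 1000
    ame_draws: int = 1000
    outdir: str = "runs/out"

    def __post_init__(self) -> None:
        if self.radius_mode not in ("fixed_50", "variable_90", "custom", "none"):
            raise ValueError(f"unknown radius_mode {self.radius_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        market = MarketConfig.from_dict(raw.pop("market", {}))
        return cls(market=market, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["market"] = self.market.to_dict()
        return d


def _radius_for(config: RunConfig) -> float | None:
    if config.radius_mode == "fixed_50":
        return 50.0
    if config.radius_mode == "custom":
        return config.radius_miles
    if config.radius_mode == "none":
        return None
    return None  # variable_90 handled via market radii


def descriptive_stats(dataset: pd.DataFrame, population_sd: bool = True) -> pd.DataFrame:
    """Means and SDs of patient, surgeon-information and hospital variables
    over chosen alternatives (one row per discharge).

    Binary variables are reported in percent; SDs use the population
    (ddof=0) convention by default, so a binary column with mean p has SD
    100*sqrt(p(1-p)).
    """
    chosen = dataset[dataset["chosen"] == 1]
    ddof = 0 if population_sd else 1
    rows = []
    for col in ("distance", "bed_size", *_PERCENT_COLS):
        if col not in chosen.columns:
            continue
        x = chosen[col].to_numpy(float)
        scale = 100.0 if col in _PERCENT_COLS else 1.0
        rows.append((col, scale * float(x.mean()), scale * float(x.std(ddof=ddof))))
    return pd.DataFrame(rows, columns=["variable", "mean", "sd"])


def _build_dataset(
    study: SyntheticStudy, config: RunConfig
) -> tuple[pd.DataFrame, choice_sets.ExclusionAudit]:
    """Choice sets + quality linkage -> assembled long dataset."""
    panel = quality_linkage.build_quality_panel(
        study.reviews,
        study.report_cards,
        study.surgeons["surgeon_id"],
        range(study.config.study_quarters),
    )
    patients = study.discharges.copy()
    radii = None
    if config.radius_mode == "variable_90":
        radii = choice_sets.market_radii(study.discharges, config.coverage)
    rows, audit = choice_sets.build_choice_rows(
        patients,
        study.roster_at,
        radius=_radius_for(config),
        radii=radii,
    )
    data = choice_sets.assemble_long_dataset(rows, panel)
    return data, audit


def run_pipeline(
    config: RunConfig, stages: Sequence[str] = ("simulate", "link", "build", "fit", "post")
) -> dict:
    """Execute the requested stages, writing artifacts under ``config.outdir``.

    Returns a dict of artifact paths.  Any stage failure aborts with the
    stage named; artifacts of completed stages persist.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    artifacts: dict[str, str] = {"config": str(out / "config.yaml")}
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    study: SyntheticStudy | None = None
    dataset: pd.DataFrame | None = None
    main_fit = None
    stage = "simulate"
    try:
        if "simulate" in stages:
            study = synthetic_market.generate_market(config.market)
            truth = synthetic_market.default_true_parameters(
                study.surgeons["surgeon_id"], seed=config.seed
            )
            study = synthetic_market.simulate_choices(study, truth, seed=config.seed + 1)
            synthetic_market.save_study(study, out / "market")
            artifacts["market"] = str(out / "market")
            logger.info("simulate: %d discharges", len(study.discharges))
        else:
            study = synthetic_market.load_study(out / "market")

        stage = "link"
        if "link" in stages:
            panel = quality_linkage.build_quality_panel(
                study.reviews,
                study.report_cards,
                study.surgeons["surgeon_id"],
                range(study.config.study_quarters),
            )
            quality_linkage.write_panel_csv(panel, out / "panel.csv")
            artifacts["panel"] = str(out / "panel.csv")
            logger.info("link: %d panel cells", len(panel))

        stage = "build"
        if {"build", "fit", "post", "interactions"} & set(stages):
            dataset, audit = _build_dataset(study, config)
            fdict = dict(config.filters)
            if any(fdict.values()):
                dataset, filter_audit = choice_sets.apply_filters(dataset, **fdict)
                filter_audit.to_json(out / "filter_audit.json")
                artifacts["filter_audit"] = str(out / "filter_audit.json")
            choice_sets.write_long_csv(dataset, out / "long.csv")
            audit.to_json(out / "audit.json")
            unrestricted, _ = _build_dataset(
                study, dataclasses.replace(config, radius_mode="none")
            )
            desc = pd.concat(
                [
                    descriptive_stats(unrestricted).assign(sample="unrestricted"),
                    descriptive_stats(dataset).assign(sample="restricted"),
                ]
            )
            desc.to_csv(out / "descriptive.csv", index=False, float_format="%.10g")
            artifacts["long"] = str(out / "long.csv")
            artifacts["audit"] = str(out / "audit.json")
            artifacts["descriptive"] = str(out / "descriptive.csv")
            logger.info(
                "build: %d rows, %d patients retained, %d excluded",
                len(dataset), audit.n_retained, audit.n_excluded,
            )

        stage = "fit"
        if "fit" in stages:
            main_fit = fit_mixed(
                dataset,
                ModelSpec(),
                draws=config.draws,
                method=config.draw_method,
                seed=config.seed,
                tol=config.tol,
                max_iter=config.max_iter,
            )
            main_fit.to_json(out / "fit.json")
            (out / "fit_table.txt").write_text(main_fit.summary_table() + "\n")
            artifacts["fit"] = str(out / "fit.json")
            artifacts["fit_table"] = str(out / "fit_table.txt")
            logger.info("fit: loglik %.3f converged %s", main_fit.loglik, main_fit.converged)

        stage = "post"
        if "post" in stages:
            if main_fit is None:
                raise RuntimeError("post stage requires the fit stage")
            edata = EstimationData(dataset, main_fit.spec)
            shares = {}
            for a in main_fit.spec.random_attrs:
                sd = main_fit.sd(a)
                if sd > 0:
                    sp = postestimation.share_preferring(main_fit.mu(a), sd)
                    shares[a] = {"share": sp.share, "complement": sp.complement}
            wtt = {}
            for a in QUALITY_ATTRS:
                w = postestimation.willingness_to_travel(main_fit, a)
                wtt[a] = {"miles": w.miles, "se": w.se}
            baseline = postestimation.baseline_choice_probability(edata)
            ames = [
                postestimation.ame_bootstrap(
                    main_fit, edata, a,
                    n_boot=config.n_boot, seed=config.seed, n_draws=config.ame_draws,
                )
                for a in ("high_online", "high_report")
            ]
            postestimation.write_post_report(out / "post.json", shares, wtt, ames, baseline)
            artifacts["post"] = str(out / "post.json")

        stage = "robustness"
        if "robustness" in stages:
            variants = {
                "exclude_exited": dict(filters={"exclude_exited": True}),
                "variable_radius": dict(radius_mode="variable_90"),
                "nonemergency": dict(filters={"nonemergency_only": True}),
                "nonreferral": dict(filters={"nonreferral_only": True}),
            }
            rob_dir = out / "robustness"
            rob_dir.mkdir(exist_ok=True)
            for name, overrides in variants.items():
                vconf = dataclasses.replace(config, **overrides)
                vdata, vaudit = _build_dataset(study, vconf)
                if any(vconf.filters.values()):
                    vdata, _ = choice_sets.apply_filters(vdata, **vconf.filters)
                vfit = fit_mixed(
                    vdata, ModelSpec(),
                    draws=config.draws, method=config.draw_method,
                    seed=config.seed, tol=config.tol, max_iter=config.max_iter,
                )
                vfit.to_json(rob_dir / f"{name}.json")
                vaudit.to_json(rob_dir / f"{name}_audit.json")
            artifacts["robustness"] = str(rob_dir)

        stage = "interactions"
        if "interactions" in stages:
            ispec = ModelSpec(interactions=QUALITY_ATTRS)
            ifit = fit_mixed(
                dataset, ispec,
                draws=config.draws, method=config.draw_method,
                seed=config.seed, tol=config.tol, max_iter=config.max_iter,
            )
            ifit.to_json(out / "fit_interactions.json")
            start_year = 2008
            years = range(
                start_year, start_year + study.config.study_quarters // 4
            )
            frames = []
            for a in ("high_online", "high_report"):
                ye = postestimation.year_effects(ifit, a, years, origin_year=start_year)
                frames.append(ye.assign(attribute=a))
            pd.concat(frames).to_csv(
                out / "year_effects.csv", index=False, float_format="%.10g"
            )
            artifacts["fit_interactions"] = str(out / "fit_interactions.json")
            artifacts["year_effects"] = str(out / "year_effects.csv")
    except Exception:
        logger.exception("pipeline aborted at stage %r", stage)
        with open(out / "FAILED.json", "w") as fh:
            json.dump({"stage": stage}, fh)
        raise

    with open(out / "artifacts.json", "w") as fh:
        json.dump(artifacts, fh, indent=2, sort_keys=True)
    return artifacts
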