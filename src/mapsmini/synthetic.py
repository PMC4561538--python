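"""Synthetic study generator with the statistical structure the analysis assumes.

The generator emulates a multi-site observational design: participants of
four age groups nested in census block groups, block groups stratified by a
binary macrolevel walkability index, one audited quarter-mile route per
participant (1+ street segments, 0+ crossings) with item prevalences that
depend on the walkability stratum, survey outcomes produced by a latent
linear model on the route's percent-of-maximum score with block-group
random intercepts, and epoch-level accelerometer streams with injected
supra-cutpoint activity at a rate increasing in the score.

Outcomes are generated latent-linear and then mapped onto each
instrument's scale (ordinal binning for 0-5 frequency scales, non-negative
rounding for counts and minutes): the generator mirrors what the mixed
model assumes, not what the world is.  Full configured truth is retained
for parameter-recovery experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .accelerometry import (
    AccelConfig,
    AgeGroup,
    EpochSeries,
    LocationIntervals,
    detect_nonwear,
    mean_daily_mvpa,
    summarize_days,
    write_epoch_csv,
    write_intervals_csv,
)
from .audit import (
    AuditDataset,
    Category,
    CrossingObservation,
    ItemDefinition,
    Level,
    RouteObservation,
    SegmentObservation,
    default_catalog,
    write_audit_tables,
)
from .outcomes import assemble_analysis_table
from .scoring import ScoreConfig, score_dataset, scores_to_frame, total_score
from .validation import ModelSpec, fit_item_model

__all__ = [
    "OutcomeEffect",
    "AccelSimConfig",
    "SimConfig",
    "SimulatedStudy",
    "default_item_prevalence",
    "default_effects",
    "scaled_sim_config",
    "simulate_study",
    "simulate_epochs",
    "accel_summary_frame",
    "analysis_table_from_study",
    "recovery_report",
    "write_study",
]

AGE_GROUPS = [g.value for g in AgeGroup]

#: Study-sized cohorts (children, adolescents, adults, older adults).
STUDY_PARTICIPANTS = {"child": 758, "adolescent": 897, "adult": 1655, "older_adult": 367}

#: Nonwhite fraction by age group, matching the cohorts' reported marginals.
NONWHITE_FRACTION = {"child": 0.314, "adolescent": 0.333, "adult": 0.242, "older_adult": 0.162}

AGE_RANGES = {"child": (6, 11), "adolescent": (12, 16), "adult": (30, 55),
              "older_adult": (66, 90)}


@dataclass
class OutcomeEffect:
    """Latent linear model for one (age group, outcome) pair:
    ``y = intercept + beta_score * percent_of_max + covariate terms
    + N(0, tau) block-group intercept + N(0, sigma) noise``."""

    intercept: float
    beta_score: float  # outcome units per percent-of-max point
    sigma: float       # residual SD
    tau: float         # block-group intercept SD
    covariates: dict[str, float] = field(default_factory=dict)


def default_effects() -> dict[tuple[str, str], OutcomeEffect]:
    """Plausible modest effects on each instrument's own scale.  Transport
    effects are positive in every group (the pattern the audit total score
    shows); adolescent neighborhood activity is weakly negative."""
    return {
        ("child", "transport"): OutcomeEffect(0.8, 0.015, 0.9, 0.25,
            {"sex": 0.10, "nonwhite": -0.10, "walkability_high": 0.10}),
        ("adolescent", "transport"): OutcomeEffect(0.7, 0.015, 0.9, 0.25,
            {"sex": 0.10, "walkability_high": 0.10}),
        ("adult", "transport"): OutcomeEffect(0.8, 0.020, 1.2, 0.30,
            {"sex": 0.20, "education_college": 0.10, "walkability_high": 0.20}),
        ("older_adult", "transport"): OutcomeEffect(0.05, 0.012, 0.7, 0.15,
            {"walkability_high": 0.10, "mobility_impairment": 0.003}),
        ("child", "leisure"): OutcomeEffect(1.8, 0.010, 1.0, 0.25,
            {"sex": 0.10, "walkability_high": 0.05}),
        ("adolescent", "leisure"): OutcomeEffect(1.8, -0.005, 1.0, 0.25, {}),
        ("adult", "leisure"): OutcomeEffect(45.0, 0.60, 12.0, 4.0,
            {"sex": -3.0, "education_college": 2.0, "walkability_high": 2.0,
             "age": -0.10}),
        ("older_adult", "leisure"): OutcomeEffect(50.0, 0.20, 25.0, 8.0,
            {"mobility_impairment": 0.10}),
    }


def default_item_prevalence() -> dict[str, tuple[float, float]]:
    """Per-item response probability (low-walkability, high-walkability
    stratum).  Chosen so percent-of-max spans a wide range with the bulk of
    routes scoring well under half of the maximum, as real streetscape
    audits do."""
    return {
        "public_park": (0.15, 0.30),
        "transit_stops": (0.25, 0.55),
        "street_lights": (0.45, 0.65),
        "benches": (0.10, 0.30),
        "building_maintenance": (0.55, 0.70),
        "graffiti_absent": (0.75, 0.65),
        "crosswalk": (0.25, 0.50),
        "curb_cuts": (0.45, 0.70),
        "crossing_signal": (0.20, 0.40),
        "commercial": (0.20, 0.45),
        "sidewalk": (0.55, 0.80),
        "sidewalk_buffer": (0.30, 0.45),
        "trees_coverage": (0.40, 0.55),
        "trip_hazards_absent": (0.60, 0.65),
    }


@dataclass
class AccelSimConfig:
    """Accelerometer emulation: 7 monitoring days starting on a Monday,
    device worn 07:00-20:00 (zeros overnight), low sub-cutpoint background
    counts while worn, and Poisson-injected supra-cutpoint epochs whose
    daily rate rises with the participant's audit score.  Children's
    neighborhood time is reported as a fixed 16:00-18:00 interval each day."""

    start_date: str = "2010-04-05"  # a Monday
    wear_start_hour: int = 7
    wear_end_hour: int = 20
    zero_prob_worn: float = 0.25
    background_cpm_scale: float = 200.0
    neighborhood_window: tuple[int, int] = (16, 18)
    # injected MVPA epochs/day: base + slope * percent_of_max
    mvpa_base: dict[str, float] = field(default_factory=lambda: {
        "child": 30.0, "adolescent": 40.0, "older_adult": 8.0})
    mvpa_slope: dict[str, float] = field(default_factory=lambda: {
        "child": 0.30, "adolescent": 0.30, "older_adult": 0.12})
    # children additionally get neighborhood-window bouts tied to the score
    neighborhood_base: float = 4.0
    neighborhood_slope: float = 0.12


@dataclass
class SimConfig:
    seed: int = 0
    n_block_groups: int = 100
    participants: dict[str, int] = field(default_factory=lambda: dict(STUDY_PARTICIPANTS))
    walkability_high_fraction: float = 0.5
    mean_segments: float = 3.0   # segments per route ~ 1 + Poisson(mean - 1)
    mean_crossings: float = 1.5  # crossings per route ~ Poisson(mean); mass at 0
    item_prevalence: dict[str, tuple[float, float]] = field(
        default_factory=default_item_prevalence)
    bike_level_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"low": (0.85, 0.12, 0.03), "high": (0.60, 0.30, 0.10)})
    effects: dict[tuple[str, str], OutcomeEffect] = field(default_factory=default_effects)
    accel: AccelSimConfig = field(default_factory=AccelSimConfig)
    simulate_accel: bool = True

    def __post_init__(self) -> None:
        if all(n <= 0 for n in self.participants.values()):
            raise ValueError("infeasible config: no participants in any age group")
        for item, (plo, phi) in self.item_prevalence.items():
            if not (0 <= plo <= 1 and 0 <= phi <= 1):
                raise ValueError(f"prevalence for {item!r} outside [0, 1]")
        for eff in self.effects.values():
            if eff.sigma < 0 or eff.tau < 0:
                raise ValueError("variance components must be non-negative")
        if not 0 <= self.walkability_high_fraction <= 1:
            raise ValueError("walkability_high_fraction outside [0, 1]")


def scaled_sim_config(seed: int = 0, participants_per_group: int = 200,
                      n_block_groups: int = 50,
                      simulate_accel: bool = False) -> SimConfig:
    """Desk-scale configuration used for repeated-simulation experiments:
    ~200 participants per age group in 50 block groups, accelerometer
    streams off (the survey outcomes drive parameter recovery)."""
    return SimConfig(
        seed=seed,
        n_block_groups=n_block_groups,
        participants={g: participants_per_group for g in AGE_GROUPS},
        simulate_accel=simulate_accel,
    )


@dataclass
class SimulatedStudy:
    audit: AuditDataset
    survey: pd.DataFrame
    covariates: pd.DataFrame
    epochs: dict[str, EpochSeries]
    intervals: dict[str, LocationIntervals]
    truth: dict
    config: SimConfig


# ---------------------------------------------------------------------------


def _rng(cfg_seed: int, *key: int) -> np.random.Generator:
    # substream keyed by (seed, component [, participant index])
    return np.random.default_rng([cfg_seed & 0x7FFFFFFF, *key])


def _simulate_route(pid: str, bg_id: str, stratum: str, cfg: SimConfig,
                    catalog: list[ItemDefinition],
                    rng: np.random.Generator) -> RouteObservation:
    col = 0 if stratum == "low" else 1
    n_seg = 1 + rng.poisson(max(cfg.mean_segments - 1.0, 0.0))
    n_cross = rng.poisson(cfg.mean_crossings)
    route_resp: dict[str, float] = {}
    segments = [SegmentObservation(i, {}) for i in range(n_seg)]
    crossings = [CrossingObservation(i, {}) for i in range(n_cross)]
    for it in catalog:
        if it.category is Category.BICYCLE_FACILITIES:
            probs = cfg.bike_level_probs[stratum]
            route_resp[it.item_id] = float(rng.choice([0, 1, 2], p=probs))
            continue
        p = cfg.item_prevalence[it.item_id][col]
        if it.level is Level.ROUTE:
            route_resp[it.item_id] = float(rng.random() < p)
        elif it.level is Level.SEGMENT:
            draws = rng.random(n_seg) < p
            for seg, v in zip(segments, draws):
                seg.responses[it.item_id] = float(v)
        else:
            draws = rng.random(n_cross) < p
            for cr, v in zip(crossings, draws):
                cr.responses[it.item_id] = float(v)
    return RouteObservation(participant_id=pid, route_id=f"R-{pid}",
                            block_group_id=bg_id, route_responses=route_resp,
                            segments=segments, crossings=crossings)


def _ordinal_items(latent: float, n_items: int, rng: np.random.Generator,
                   item_sd: float = 0.8, lo: int = 0, hi: int = 5) -> np.ndarray:
    raw = latent + rng.normal(0.0, item_sd, size=n_items)
    return np.clip(np.round(raw), lo, hi).astype(int)


def simulate_epochs(participant_id: str, age_group: str, age_years: float,
                    percent_of_max: float, cfg: SimConfig,
                    rng: np.random.Generator) -> tuple[EpochSeries, LocationIntervals]:
    """Seven days of epoch counts for one participant, plus the reported
    neighborhood time intervals (one window per day)."""
    ac = cfg.accel
    group = AgeGroup(age_group)
    accel_cfg = AccelConfig.for_age_group(group, age_years)
    epoch_len = 30 if group in (AgeGroup.CHILD, AgeGroup.ADOLESCENT) else 60
    per_day = 86400 // epoch_len
    n = per_day * 7
    start = pd.Timestamp(ac.start_date)
    ts = start + pd.to_timedelta(np.arange(n) * epoch_len, unit="s")
    ts = pd.DatetimeIndex(ts)
    hours = ts.hour.to_numpy()
    worn = (hours >= ac.wear_start_hour) & (hours < ac.wear_end_hour)

    counts = np.zeros(n, dtype=np.int64)
    n_worn = int(worn.sum())
    cpm = rng.exponential(ac.background_cpm_scale, size=n_worn)
    cpm = np.minimum(cpm, 0.75 * accel_cfg.cutpoint_counts_per_min)
    cpm[rng.random(n_worn) < ac.zero_prob_worn] = 0.0
    counts[worn] = np.round(cpm * epoch_len / 60.0).astype(np.int64)

    def inject(candidate_idx: np.ndarray, n_epochs: int) -> None:
        if n_epochs <= 0 or len(candidate_idx) == 0:
            return
        chosen = rng.choice(candidate_idx, size=min(n_epochs, len(candidate_idx)),
                            replace=False)
        boost_cpm = accel_cfg.cutpoint_counts_per_min * (1.3 + rng.exponential(0.5, len(chosen)))
        counts[chosen] = np.round(boost_cpm * epoch_len / 60.0).astype(np.int64)

    day_index = np.arange(n) // per_day
    rate = ac.mvpa_base[group.value] + ac.mvpa_slope[group.value] * percent_of_max
    nb_lo, nb_hi = ac.neighborhood_window
    in_nb = (hours >= nb_lo) & (hours < nb_hi)
    for d in range(7):
        in_day = day_index == d
        inject(np.flatnonzero(in_day & worn), rng.poisson(rate))
        if group is AgeGroup.CHILD:
            nb_rate = ac.neighborhood_base + ac.neighborhood_slope * percent_of_max
            inject(np.flatnonzero(in_day & worn & in_nb), rng.poisson(nb_rate))

    series = EpochSeries(participant_id=participant_id, epoch_length=epoch_len,
                         timestamps=ts, counts=counts)
    intervals = LocationIntervals(
        participant_id=participant_id,
        intervals=[(start + pd.Timedelta(days=d, hours=nb_lo),
                    start + pd.Timedelta(days=d, hours=nb_hi)) for d in range(7)])
    return series, intervals


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Generate a complete synthetic study, deterministic in ``cfg.seed``."""
    catalog = default_catalog()
    rng_design = _rng(cfg.seed, 1)
    rng_audit = _rng(cfg.seed, 2)
    rng_survey = _rng(cfg.seed, 3)

    # block groups stratified by the binary walkability index
    n_bg = cfg.n_block_groups
    bg_ids = [f"BG{i:04d}" for i in range(n_bg)]
    n_high = int(round(cfg.walkability_high_fraction * n_bg))
    strata = np.array(["low"] * n_bg, dtype=object)
    strata[rng_design.choice(n_bg, size=n_high, replace=False)] = "high"

    prefix = {"child": "C", "adolescent": "T", "adult": "P", "older_adult": "S"}
    participants: list[dict] = []
    for group in AGE_GROUPS:
        n = cfg.participants.get(group, 0)
        lo_age, hi_age = AGE_RANGES[group]
        bgi = rng_design.integers(0, n_bg, size=n)
        ages = rng_design.uniform(lo_age, hi_age + 1, size=n).astype(int)
        sex = rng_design.random(n) < 0.5
        edu = rng_design.random(n) < 0.55
        nonwhite = rng_design.random(n) < NONWHITE_FRACTION[group]
        mobility = np.clip(rng_design.normal(70, 15, size=n), 0, 100)
        for i in range(n):
            participants.append({
                "participant_id": f"{prefix[group]}{i + 1:05d}",
                "age_group": group,
                "block_group_id": bg_ids[bgi[i]],
                "bg_index": int(bgi[i]),
                "age": int(ages[i]),
                "sex": int(sex[i]),
                "education_college": int(edu[i]),
                "nonwhite": int(nonwhite[i]),
                "walkability_high": int(strata[bgi[i]] == "high"),
                "mobility_impairment": (round(float(mobility[i]), 1)
                                        if group == "older_adult" else np.nan),
            })

    # audited routes and realized percent-of-max scores
    routes = []
    percent = {}
    score_cfg = ScoreConfig(catalog=catalog)
    for rec in participants:
        stratum = "high" if rec["walkability_high"] else "low"
        route = _simulate_route(rec["participant_id"], rec["block_group_id"],
                                stratum, cfg, catalog, rng_audit)
        routes.append(route)
        percent[rec["participant_id"]] = total_score(route, score_cfg).percent_of_max
    audit = AuditDataset(catalog=catalog, routes=routes)

    # block-group random intercepts, one draw per (group, outcome) pair
    block_intercepts = {
        key: rng_survey.normal(0.0, eff.tau, size=n_bg)
        for key, eff in sorted(cfg.effects.items())
    }

    def latent(rec: dict, outcome: str) -> float:
        key = (rec["age_group"], outcome)
        eff = cfg.effects[key]
        y = eff.intercept + eff.beta_score * percent[rec["participant_id"]]
        for cov, beta in eff.covariates.items():
            v = rec.get(cov, 0.0)
            y += beta * (0.0 if v is None or (isinstance(v, float) and np.isnan(v)) else v)
        y += block_intercepts[key][rec["bg_index"]]
        return y + rng_survey.normal(0.0, eff.sigma)

    survey_rows = []
    for rec in participants:
        group = rec["age_group"]
        row: dict = {"participant_id": rec["participant_id"], "age_group": group}
        y_t = latent(rec, "transport")
        y_l = latent(rec, "leisure")
        if group in ("child", "adolescent"):
            for j, v in enumerate(_ordinal_items(y_t, 9, rng_survey), start=1):
                row[f"dest_freq_{j}"] = v
            for j, v in enumerate(_ordinal_items(y_l, 5, rng_survey), start=1):
                row[f"place_freq_{j}"] = v
        elif group == "adult":
            row["gpaq_transport_days"] = int(np.clip(round(y_t), 0, 7))
            row["gpaq_leisure_minutes"] = int(max(round(y_l), 0))
        else:
            row["champs_walk_bike_per_week"] = max(round(y_t * 2) / 2.0, 0.0)
            row["champs_leisure_walk_minutes"] = int(max(round(y_l), 0))
        survey_rows.append(row)
    survey_cols = (["participant_id", "age_group"]
                   + [f"dest_freq_{j}" for j in range(1, 10)]
                   + [f"place_freq_{j}" for j in range(1, 6)]
                   + ["gpaq_transport_days", "gpaq_leisure_minutes",
                      "champs_walk_bike_per_week", "champs_leisure_walk_minutes"])
    survey = pd.DataFrame(survey_rows).reindex(columns=survey_cols)

    epochs: dict[str, EpochSeries] = {}
    intervals: dict[str, LocationIntervals] = {}
    if cfg.simulate_accel:
        for idx, rec in enumerate(participants):
            if rec["age_group"] == "adult":
                continue  # parents did not wear accelerometers
            rng_p = _rng(cfg.seed, 4, idx)
            series, iv = simulate_epochs(
                rec["participant_id"], rec["age_group"], rec["age"],
                percent[rec["participant_id"]], cfg, rng_p)
            epochs[rec["participant_id"]] = series
            intervals[rec["participant_id"]] = iv

    covariates = pd.DataFrame(participants).drop(columns=["bg_index"])
    truth = {
        "percent_of_max": percent,
        "effects": {f"{g}.{o}": vars(eff) | {"covariates": dict(eff.covariates)}
                    for (g, o), eff in cfg.effects.items()},
        "block_group_strata": {bg: s for bg, s in zip(bg_ids, strata)},
        "block_intercepts": {f"{g}.{o}": b.tolist()
                             for (g, o), b in block_intercepts.items()},
    }
    return SimulatedStudy(audit=audit, survey=survey, covariates=covariates,
                          epochs=epochs, intervals=intervals, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Downstream assembly helpers


def accel_summary_frame(study: SimulatedStudy) -> Optional[pd.DataFrame]:
    """Run the accelerometry pipeline over every generated epoch stream and
    return per-participant mean daily MVPA summaries."""
    if not study.epochs:
        return None
    ages = study.covariates.set_index("participant_id")["age"]
    groups = study.covariates.set_index("participant_id")["age_group"]
    rows = []
    for pid, series in study.epochs.items():
        acfg = AccelConfig.for_age_group(groups[pid], float(ages[pid]))
        mask = detect_nonwear(series, acfg.nonwear_window)
        summaries = summarize_days(series, mask, acfg,
                                   intervals=study.intervals.get(pid))
        rows.append({
            "participant_id": pid,
            "n_valid_days": sum(s.valid for s in summaries),
            "mvpa_total": mean_daily_mvpa(summaries, "mvpa_minutes"),
            "mvpa_nonschool": mean_daily_mvpa(summaries, "mvpa_minutes_windowed"),
            "mvpa_neighborhood": mean_daily_mvpa(summaries, "mvpa_minutes_neighborhood"),
        })
    return pd.DataFrame(rows)


def analysis_table_from_study(study: SimulatedStudy,
                              score_cfg: Optional[ScoreConfig] = None) -> pd.DataFrame:
    """Score the audit, derive survey outcomes, process accelerometry, and
    assemble the per-participant analysis table."""
    scores = scores_to_frame(score_dataset(study.audit, score_cfg))
    return assemble_analysis_table(scores, study.survey, study.covariates,
                                   accel=accel_summary_frame(study))


def recovery_report(cfg: SimConfig, n_reps: int, outcome: str = "leisure",
                    age_group: str = "adult", alpha: float = 0.05) -> dict:
    """Repeatedly simulate, score, assemble, and fit; compare the estimated
    score effect with the generating value.

    Returns bias, relative bias, RMSE, 95% CI coverage, and the rejection
    rate at ``alpha`` (under a zero generating effect the rejection rate
    estimates the type-I error)."""
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    true_beta = cfg.effects[(age_group, outcome)].beta_score
    betas, ses, pvals = [], [], []
    for rep in range(n_reps):
        rep_cfg = replace(cfg, seed=(cfg.seed + 1_000_003 * (rep + 1)) % (2**31))
        study = simulate_study(rep_cfg)
        table = analysis_table_from_study(study)
        spec = ModelSpec.for_group(outcome, "percent_of_max", age_group, alpha=alpha)
        res = fit_item_model(table, spec)
        betas.append(res.beta)
        ses.append(res.se)
        pvals.append(res.p_value)
    betas = np.asarray(betas)
    ses = np.asarray(ses)
    pvals = np.asarray(pvals)
    covered = np.abs(betas - true_beta) <= 1.959963984540054 * ses
    out = {
        "outcome": outcome,
        "age_group": age_group,
        "n_reps": n_reps,
        "true_beta": true_beta,
        "mean_beta": float(betas.mean()),
        "bias": float(betas.mean() - true_beta),
        "relative_bias": (float((betas.mean() - true_beta) / true_beta)
                          if true_beta != 0 else None),
        "rmse": float(np.sqrt(np.mean((betas - true_beta) ** 2))),
        "ci95_coverage": float(covered.mean()),
        "rejection_rate": float((pvals <= alpha).mean()),
        "mc_se_rejection": float(np.sqrt(alpha * (1 - alpha) / n_reps)),
    }
    return out


# ---------------------------------------------------------------------------
# Bundle writer


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the four CSV bundles plus the truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_audit_tables(study.audit, out_dir)
    paths["survey"] = out_dir / "survey.csv"
    study.survey.to_csv(paths["survey"], index=False)
    paths["covariates"] = out_dir / "covariates.csv"
    study.covariates.to_csv(paths["covariates"], index=False)
    paths["epochs"] = write_epoch_csv(study.epochs, out_dir / "epochs.csv")
    paths["intervals"] = write_intervals_csv(study.intervals, out_dir / "intervals.csv")
    paths["truth"] = out_dir / "truth.json"
    paths["truth"].write_text(json.dumps(study.truth, indent=1, sort_keys=True))
    return paths
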