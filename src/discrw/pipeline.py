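"""End-to-end orchestration: cohort simulation through model comparison.

Stages: simulate judgments for a cohort, run both model variants over the
learning-rate grid, synthesize per-session BOLD from a chosen ground-truth
model, fit the five-regressor GLM for every (subject, session, alpha,
variant), and compare variants with paired tests.  All stage seeds derive
deterministically from the master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import glm_analysis, rw_models, synthetic_data, task_design
from .rw_models import ALPHA_GRID, ModelParams, run_model
from .synthetic_data import Cohort, GroundTruth, simulate_cohort, synthesize_bold

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration; ``errors`` lists every violation."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration: " + "; ".join(errors))


@dataclass(frozen=True)
class PipelineConfig:
    n_subjects: int = 23
    n_sessions: int = 4
    sessions_for_comparison: tuple[int, ...] = (1, 2, 3)
    alpha_grid: tuple[float, ...] = ALPHA_GRID
    generating_variant: str = "WITH"
    generating_alpha: float = 0.05
    beta_true: tuple[float, ...] = (1.0, 1.0, 0.5, 1.0, 0.5)
    noise_sd: float = 0.5
    ar1_coef: float = 0.3
    drift_amplitude: float = 1.0
    accuracy_high: float = 0.9
    accuracy_low: float = 0.6
    update_mode: str = "judged_only"
    tr: float = task_design.DEFAULT_TR
    n_volumes: int = task_design.DEFAULT_N_VOLUMES
    post_delivery_period_s: float = task_design.DEFAULT_POST_DELIVERY_S
    master_seed: int = 0


def _validators(cfg: PipelineConfig) -> list[str]:
    errors = []
    if cfg.n_subjects < 1:
        errors.append(f"n_subjects must be >= 1, got {cfg.n_subjects}")
    if not 1 <= cfg.n_sessions <= 4:
        errors.append(f"n_sessions must be in 1..4, got {cfg.n_sessions}")
    if len(cfg.alpha_grid) == 0:
        errors.append("alpha_grid must be non-empty")
    for a in cfg.alpha_grid:
        if not 0.0 < a <= 1.0:
            errors.append(f"alpha_grid entry {a} outside (0, 1]")
    if not 0.0 < cfg.generating_alpha <= 1.0:
        errors.append(f"generating_alpha {cfg.generating_alpha} outside (0, 1]")
    if cfg.generating_variant not in ("WITH", "WITHOUT", "none"):
        errors.append(f"generating_variant must be WITH, WITHOUT or none")
    if not set(cfg.sessions_for_comparison) <= set(range(1, cfg.n_sessions + 1)):
        errors.append(
            f"sessions_for_comparison {cfg.sessions_for_comparison} not a subset of "
            f"simulated sessions 1..{cfg.n_sessions}"
        )
    if cfg.noise_sd < 0:
        errors.append(f"noise_sd must be >= 0, got {cfg.noise_sd}")
    if not 0 <= cfg.ar1_coef <= 0.95:
        errors.append(f"ar1_coef must be in [0, 0.95], got {cfg.ar1_coef}")
    if cfg.drift_amplitude < 0:
        errors.append(f"drift_amplitude must be >= 0, got {cfg.drift_amplitude}")
    if len(cfg.beta_true) != 5:
        errors.append(f"beta_true must have 5 entries, got {len(cfg.beta_true)}")
    if not 0.5 <= cfg.accuracy_low < cfg.accuracy_high <= 1.0:
        errors.append(
            f"accuracies must satisfy 0.5 <= low < high <= 1, got "
            f"low={cfg.accuracy_low}, high={cfg.accuracy_high}"
        )
    if cfg.update_mode not in rw_models.UPDATE_MODES:
        errors.append(f"update_mode must be one of {rw_models.UPDATE_MODES}")
    if cfg.tr <= 0:
        errors.append("tr must be positive")
    if cfg.n_volumes < 4:
        errors.append("n_volumes must be >= 4")
    return errors


_TUPLE_FIELDS = {"sessions_for_comparison", "alpha_grid", "beta_true"}


def validate_config(raw: dict) -> PipelineConfig:
    """Build a config from a key-value document, reporting all violations at once."""
    known = {f.name for f in fields(PipelineConfig)}
    errors = [f"unknown config key: {k!r}" for k in raw if k not in known]
    clean = {k: v for k, v in raw.items() if k in known}
    for key in _TUPLE_FIELDS & clean.keys():
        clean[key] = tuple(clean[key])
    try:
        cfg = PipelineConfig(**clean)
    except (TypeError, ValueError) as exc:
        raise ConfigError(errors + [str(exc)])
    errors.extend(_validators(cfg))
    if errors:
        raise ConfigError(errors)
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    out = asdict(cfg)
    for key in _TUPLE_FIELDS:
        out[key] = list(out[key])
    return out


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic per-stage seed: SeedSequence over (master, stage key...)."""
    return int(np.random.SeedSequence([int(master_seed), *map(int, key)]).generate_state(1)[0])


# stage indices for derive_seed
_STAGE_BEHAVIOR = 0
_STAGE_BOLD = 1


@dataclass
class PipelineReport:
    fig5_vr_dominance: pd.DataFrame
    fig6_positive_pe: pd.DataFrame
    fig8_effect_by_alpha: pd.DataFrame
    fig9_effect_by_session: pd.DataFrame
    effects: pd.DataFrame
    provenance: dict


def _truth_from_config(cfg: PipelineConfig) -> GroundTruth:
    return GroundTruth(
        generating_variant=cfg.generating_variant,
        alpha=cfg.generating_alpha,
        beta_true=tuple(cfg.beta_true),
        noise_sd=cfg.noise_sd,
        ar1_coef=cfg.ar1_coef,
        drift_amplitude=cfg.drift_amplitude,
    )


def simulate_cohort_from_config(cfg: PipelineConfig) -> Cohort:
    return simulate_cohort(
        n_subjects=cfg.n_subjects,
        n_sessions=cfg.n_sessions,
        master_seed=derive_seed(cfg.master_seed, _STAGE_BEHAVIOR),
        accuracy_high=cfg.accuracy_high,
        accuracy_low=cfg.accuracy_low,
        tr=cfg.tr,
        n_volumes=cfg.n_volumes,
        post_delivery_s=cfg.post_delivery_period_s,
    )


def synthesize_cohort_bold(cfg: PipelineConfig, cohort: Cohort) -> dict:
    """Per (subject, session) synthetic BOLD under the configured ground truth."""
    truth = _truth_from_config(cfg)
    bold = {}
    for subject in cohort.subjects:
        sid = subject.profile.subject_id
        truth_trace = None
        if truth.generating_variant != "none":
            truth_trace = run_model(
                subject.all_trials(),
                ModelParams(
                    variant=truth.generating_variant,
                    learning_rate=truth.alpha,
                    update_mode=cfg.update_mode,
                ),
            )
        for sess, data in subject.sessions.items():
            seed = derive_seed(cfg.master_seed, _STAGE_BOLD, sid, sess)
            if truth_trace is None:
                rng = np.random.default_rng(seed)
                hp = glm_analysis.highpass_basis(cfg.n_volumes, cfg.tr)
                drift = hp @ (cfg.drift_amplitude * rng.standard_normal(hp.shape[1]))
                noise = synthetic_data.ar1_noise(cfg.n_volumes, cfg.noise_sd, cfg.ar1_coef, rng)
                ts = synthetic_data.VoxelTimeSeries(tr=cfg.tr, values=drift + noise)
            else:
                dm = glm_analysis.build_design_matrix(
                    data.design, truth_trace.for_session(sess)
                )
                ts = synthesize_bold(dm, truth, seed)
            ts.subject_id = sid
            ts.session_index = sess
            bold[(sid, sess)] = ts
    return bold


def fit_cohort_glms(
    cfg: PipelineConfig, cohort: Cohort, bold: dict, alphas=None, variants=("WITH", "WITHOUT")
) -> pd.DataFrame:
    """Effect sizes of the prediction-error regressor for every cell."""
    if alphas is None:
        alphas = cfg.alpha_grid
    rows = []
    for subject in cohort.subjects:
        sid = subject.profile.subject_id
        trials = subject.all_trials()
        for variant in variants:
            for alpha in alphas:
                trace = run_model(
                    trials,
                    ModelParams(
                        variant=variant, learning_rate=alpha, update_mode=cfg.update_mode
                    ),
                )
                for sess, data in subject.sessions.items():
                    dm = glm_analysis.build_design_matrix(
                        data.design, trace.for_session(sess)
                    )
                    res = glm_analysis.fit_glm(bold[(sid, sess)], dm)
                    rows.append(
                        {
                            "subject": sid,
                            "session": sess,
                            "alpha": alpha,
                            "variant": variant,
                            "effect_size": res.effect_size_delta,
                            "ar1_estimate": res.ar1_estimate,
                        }
                    )
    return pd.DataFrame(rows)


def _model_summary_tables(cfg: PipelineConfig, cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    fig5_rows, fig6_rows = [], []
    for variant in ("WITH", "WITHOUT"):
        for alpha in cfg.alpha_grid:
            dominance, positive = [], []
            for subject in cohort.subjects:
                trace = run_model(
                    subject.all_trials(),
                    ModelParams(
                        variant=variant, learning_rate=alpha, update_mode=cfg.update_mode
                    ),
                )
                dom = rw_models.summarize_vr_dominance(trace)
                dominance.append(dom.rename(subject.profile.subject_id))
                pos = rw_models.summarize_positive_pe(trace)
                pos["subject"] = subject.profile.subject_id
                positive.append(pos)
            dom_frame = pd.concat(dominance, axis=1)
            for sess, row in dom_frame.iterrows():
                fig5_rows.append(
                    {
                        "variant": variant,
                        "alpha": alpha,
                        "session": int(sess),
                        "pct_vr_dominant": 100.0 * row.mean(),
                        "sem_pct": 100.0 * row.std(ddof=1) / np.sqrt(row.count())
                        if row.count() > 1
                        else 0.0,
                    }
                )
            pos_frame = pd.concat(positive, ignore_index=True)
            cell = (
                pos_frame.groupby(["session", "contrast_level"])["mean_delta"]
                .agg(["mean", "sem", "count"])
                .reset_index()
            )
            for _, row in cell.iterrows():
                fig6_rows.append(
                    {
                        "variant": variant,
                        "alpha": alpha,
                        "session": int(row["session"]),
                        "contrast_level": row["contrast_level"],
                        "mean_delta": row["mean"],
                        "sem_delta": row["sem"],
                        "n_subjects": int(row["count"]),
                    }
                )
    return pd.DataFrame(fig5_rows), pd.DataFrame(fig6_rows)


def run_full_pipeline(config: PipelineConfig, out_dir=None) -> PipelineReport:
    """Execute every stage and assemble the report tables.

    Deterministic for a fixed config; when ``out_dir`` is given, interchange
    TSVs and the report JSON are written beneath it.
    """
    t0 = time.time()
    cohort = simulate_cohort_from_config(config)
    logger.info("stage=simulate_behavior subjects=%d elapsed=%.1fs", len(cohort), time.time() - t0)

    fig5, fig6 = _model_summary_tables(config, cohort)
    logger.info("stage=run_models elapsed=%.1fs", time.time() - t0)

    bold = synthesize_cohort_bold(config, cohort)
    logger.info("stage=simulate_bold elapsed=%.1fs", time.time() - t0)

    effects = fit_cohort_glms(config, cohort, bold)
    logger.info("stage=fit_glm fits=%d elapsed=%.1fs", len(effects), time.time() - t0)

    comparison = glm_analysis.compare_models(
        effects,
        sessions=config.sessions_for_comparison,
        alpha_values=list(config.alpha_grid),
        session_alpha=config.generating_alpha
        if config.generating_alpha in config.alpha_grid
        else None,
    )
    logger.info("stage=compare_models elapsed=%.1fs", time.time() - t0)

    provenance = {
        "config": config_to_dict(config),
        "master_seed": config.master_seed,
        "seed_scheme": "SeedSequence([master_seed, stage, subject, session])",
        "stages": {"behavior": _STAGE_BEHAVIOR, "bold": _STAGE_BOLD},
        "versions": _versions(),
        "elapsed_s": round(time.time() - t0, 2),
    }
    report = PipelineReport(
        fig5_vr_dominance=fig5,
        fig6_positive_pe=fig6,
        fig8_effect_by_alpha=comparison.per_alpha,
        fig9_effect_by_session=comparison.per_session,
        effects=effects,
        provenance=provenance,
    )
    if out_dir is not None:
        write_report(report, cohort, bold, Path(out_dir))
    return report


def _versions() -> dict:
    import scipy

    from . import __version__

    return {
        "discrw": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


def _write_table(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_report(report: PipelineReport, cohort: Cohort, bold: dict, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    behavior_dir = out_dir / "behavior"
    bold_dir = out_dir / "bold"
    report_dir = out_dir / "report"
    for d in (behavior_dir, bold_dir, report_dir):
        d.mkdir(parents=True, exist_ok=True)
    for subject in cohort.subjects:
        sid = subject.profile.subject_id
        for sess, data in subject.sessions.items():
            synthetic_data.write_behavior_tsv(
                data.design, data.trials, behavior_dir / f"sub-{sid:02d}_ses-{sess}_events.tsv"
            )
            synthetic_data.write_timeseries_tsv(
                bold[(sid, sess)], bold_dir / f"sub-{sid:02d}_ses-{sess}_bold.tsv"
            )
    _write_table(report.fig5_vr_dominance, report_dir / "fig5_vr_dominance.tsv")
    _write_table(report.fig6_positive_pe, report_dir / "fig6_positive_pe.tsv")
    _write_table(report.fig8_effect_by_alpha, report_dir / "fig8_effect_by_alpha.tsv")
    _write_table(report.fig9_effect_by_session, report_dir / "fig9_effect_by_session.tsv")
    _write_table(report.effects, report_dir / "effects.tsv")
    with open(report_dir / "report.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True)
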