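"""End-to-end orchestration: simulate -> preprocess -> prior -> map -> metrics -> stats.

Every artifact (phenotype table with computed metrics, tidy coefficient
table, provenance JSON) carries the config hash; a failed stage aborts with
the stage name and subject identifier before anything is written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as snio
from .battery import BatteryReport, run_battery
from .config import RunConfig
from .containers import AtlasSpec, BoldRun, EngagementMap, PriorMaps
from .mapping import compute_network_metrics, fit_posterior_map
from .preprocess import (
    build_nuisance_design,
    dct_highpass_bases,
    dvars_outliers,
    low_variance_vertices,
    regress_nuisance,
)
from .prior import estimate_prior, normalize_engagement, parcel_dual_regression, split_halves
from .synthetic import (
    NuisanceMagnitudes,
    PhenotypeSettings,
    default_prior_truth,
    make_parcel_atlas,
    simulate_bold_session,
    simulate_phenotypes,
    simulate_subject_engagement,
)

__all__ = ["PipelineResult", "preprocess_session", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory outcome of a pipeline run plus the paths written."""

    atlas: AtlasSpec
    prior: PriorMaps
    phenotypes: pd.DataFrame
    report: BatteryReport
    artifacts: dict[str, Path] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def preprocess_session(bold: BoldRun, motion: np.ndarray, config: RunConfig) -> tuple[BoldRun, np.ndarray]:
    """Apply the nuisance recipe to one session; returns (residual run, flags)."""
    n_dct = config.n_dct
    dct = dct_highpass_bases(bold.T, bold.tr, cutoff_hz=config.cutoff_hz, n_bases=n_dct)
    flags = dvars_outliers(
        bold,
        practical_cutoff_pct=config.practical_cutoff_pct,
        alpha=config.dvars_alpha,
    )
    design = build_nuisance_design(np.asarray(motion), bold, flags, dct)
    return regress_nuisance(bold, design), flags


def _stage(name: str, subject: str | None = None):
    tag = f"stage={name}" + (f" subject={subject}" if subject else "")
    logger.info("running %s", tag)
    return tag


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full synthetic-cohort analysis as configured.

    The imaging branch produces per-subject expansion and connectivity,
    which replace the generator's phenotype-table metric columns before the
    regression battery runs; subjects failing the low-variance guard are
    dropped (complete-case analysis), and their count is logged.
    """
    root = np.random.SeedSequence(config.seed)
    (atlas_seed, subj_seed, sess_seed, prior_pick_seed, pheno_seed) = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(5)
    ]
    outdir = Path(config.outdir)

    tag = _stage("atlas")
    try:
        atlas = make_parcel_atlas(config.V, config.K, seed=atlas_seed,
                                  salience_index=config.salience_index)
        prior_mean_truth, prior_var_truth = default_prior_truth(
            atlas, in_between_sd=config.in_between_sd,
            out_between_sd=config.out_between_sd,
        )
        subjects = simulate_subject_engagement(
            atlas, prior_mean_truth, prior_var_truth, config.n_subjects,
            seed=subj_seed, sessions=config.sessions_per_subject,
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at {tag}: {err}") from err

    nuisance = NuisanceMagnitudes(
        drift=config.drift, motion=config.motion, spike_rate=config.spike_rate,
        spike_amplitude=config.spike_amplitude, noise_sd=config.noise_sd,
    )

    cleaned: list[list[BoldRun]] = []
    invalid: list[bool] = []
    sess_rng = np.random.SeedSequence(sess_seed)
    session_seeds = [int(s.generate_state(1)[0] % (2**31))
                     for s in sess_rng.spawn(config.n_subjects * config.sessions_per_subject)]
    for i, subject in enumerate(subjects):
        tag = _stage("preprocess", subject=f"sub-{i:03d}")
        try:
            runs = []
            bad = False
            for s in range(config.sessions_per_subject):
                seed = session_seeds[i * config.sessions_per_subject + s]
                bold, motion = simulate_bold_session(
                    subject, atlas, config.T, config.TR, nuisance=nuisance,
                    seed=seed, signal_amplitude=config.signal_amplitude,
                )
                resid, _ = preprocess_session(bold, motion.to_numpy(), config)
                if low_variance_vertices(resid, config.low_variance_threshold).any():
                    bad = True
                runs.append(resid)
            cleaned.append(runs)
            invalid.append(bad)
        except Exception as err:
            raise RuntimeError(f"pipeline failed at {tag}: {err}") from err

    tag = _stage("prior")
    try:
        pick = np.random.default_rng(
            config.prior_seed if config.prior_seed is not None else prior_pick_seed
        )
        session_choice = [int(pick.integers(config.sessions_per_subject))
                          for _ in range(config.n_subjects)]
        pairs: list[tuple[EngagementMap, EngagementMap]] = []
        for i in range(config.n_subjects):
            run = cleaned[i][session_choice[i]]
            half_a, half_b = split_halves(run)
            pairs.append((
                normalize_engagement(parcel_dual_regression(half_a, atlas)),
                normalize_engagement(parcel_dual_regression(half_b, atlas)),
            ))
        prior = estimate_prior(pairs)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at {tag}: {err}") from err

    metrics_rows = []
    for i in range(config.n_subjects):
        tag = _stage("map", subject=f"sub-{i:03d}")
        try:
            # time-2 analysis session: the last per subject
            run = cleaned[i][-1]
            raw = normalize_engagement(parcel_dual_regression(run, atlas))
            posterior = fit_posterior_map(raw, prior)
            metrics = compute_network_metrics(
                run, posterior, atlas.salience_index,
                alpha=config.alpha, correction=config.correction,
                invalid=invalid[i],
            )
            metrics_rows.append(metrics)
        except Exception as err:
            raise RuntimeError(f"pipeline failed at {tag}: {err}") from err

    tag = _stage("stats")
    try:
        settings = PhenotypeSettings(
            noise_sd=config.phenotype_noise_sd,
            missing_t1_fraction=config.missing_t1_fraction,
        )
        table = simulate_phenotypes(config.n_subjects, settings, seed=pheno_seed)
        table["expansion"] = [m.expansion for m in metrics_rows]
        table["connectivity"] = [m.connectivity for m in metrics_rows]
        table["valid"] = [m.valid for m in metrics_rows]
        n_dropped = int((~table["valid"]).sum())
        if n_dropped:
            logger.info("dropping %d metric-invalid subjects (low-variance guard)",
                        n_dropped)
        analysis = table[table["valid"]].drop(columns=["valid"]).reset_index(drop=True)
        report = run_battery(analysis)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at {tag}: {err}") from err

    # all stages succeeded; write artifacts
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    provenance = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "prior_sessions_used": prior.n_sessions_used,
        "prior_floor_fraction": prior.floor_fraction,
        "prior_session_choice": session_choice,
        "n_metric_invalid": int(np.sum(invalid)),
        "n_subjects_analyzed": int(report.n_subjects),
        "vertex_order": "left-hemisphere-then-right, 1-based on disk",
    }
    artifacts: dict[str, Path] = {}
    table_out = table.copy()
    table_out.insert(0, "subject", [f"sub-{i:03d}" for i in range(len(table_out))])
    table_out["config_hash"] = cfg_hash
    artifacts["phenotypes"] = snio.write_phenotypes_tsv(table_out, outdir / "phenotypes.tsv")
    coef = report.coefficients.copy()
    coef["config_hash"] = cfg_hash
    coef.to_csv(outdir / "coefficients.tsv", sep="\t", index=False, float_format="%.10g")
    artifacts["coefficients"] = outdir / "coefficients.tsv"
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    artifacts["provenance"] = outdir / "provenance.json"
    np.savetxt(outdir / "prior_mean.tsv", prior.mean, delimiter="\t", fmt="%.8g")
    np.savetxt(outdir / "prior_between_var.tsv", prior.between_var, delimiter="\t", fmt="%.8g")
    artifacts["prior_mean"] = outdir / "prior_mean.tsv"
    artifacts["prior_between_var"] = outdir / "prior_between_var.tsv"
    (outdir / "summary.txt").write_text(report.summary() + "\n")
    artifacts["summary"] = outdir / "summary.txt"

    return PipelineResult(
        atlas=atlas,
        prior=prior,
        phenotypes=table,
        report=report,
        artifacts=artifacts,
        provenance=provenance,
    )
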