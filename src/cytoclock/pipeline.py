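"""End-to-end orchestration: simulate -> preprocess -> impute -> clock ->
volumetrics -> mixed-model ladder -> CCA, from one config and one seed.

A single master seed spawns independent named substreams per stage, so
changing, say, the ensemble size M leaves the simulated cohort untouched.
Every stage writes its artifacts into the run directory; a manifest records
content hashes, and a summary JSON gathers the headline quantities
(selection frequencies, ladder table, canonical-function reports).
Identical config + seed reproduce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .panel import NETWORKS
from .synthetic import (ConfigError, SimConfig, generate_cohort,
                        inject_duplicate_noise, inject_missingness)
from .preprocess import (collapse_duplicates_cv_filter, compute_balancing_weights,
                         drop_high_missingness_markers, log_transform,
                         remove_batch_effects)
from .impute import ImputationSpec, generate_ensemble
from .clock import fit_clock_ensemble, propagate_cyclo
from .volumetrics import correlation_matrix, normalize_to_tiv
from .lmm import build_model_ladder
from .cca import bartlett_sequential_test, fit_cca, rao_f_test, redundancy

log = logging.getLogger(__name__)

# fixed stage indices for substream derivation
_STAGES = {"simulate": 0, "missingness": 1, "impute": 2, "clock": 3,
           "duplicates": 4}


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) of the master seed."""
    ss = np.random.SeedSequence([int(master), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """All pipeline parameters; round-trips through YAML unchanged."""

    sim: SimConfig = field(default_factory=SimConfig)
    m_imputations: int = 50
    n_sweeps: int = 5
    n_donors: int = 5
    n_folds: int = 10
    lambda_rule: str = "1se"
    pool: str = "median"
    bin_width: float = 5.0
    cv_threshold: float = 20.0
    missing_threshold: float = 0.55
    max_gap: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        if self.m_imputations < 1:
            raise ConfigError("m_imputations must be >= 1")
        if self.lambda_rule not in ("1se", "min"):
            raise ConfigError("lambda_rule must be '1se' or 'min'")
        if self.pool not in ("median", "mean"):
            raise ConfigError("pool must be 'median' or 'mean'")
        if not (0 < self.missing_threshold < 1):
            raise ConfigError("missing_threshold must be in (0, 1)")
        if self.max_gap <= 0 or self.cv_threshold <= 0 or self.bin_width <= 0:
            raise ConfigError("max_gap, cv_threshold, bin_width must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["age_range"] = list(d["sim"]["age_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        sim = dict(sim)
        if "age_range" in sim:
            sim["age_range"] = tuple(sim["age_range"])
        return cls(sim=SimConfig(**sim), **d)

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def match_visits(visits: pd.DataFrame, cyclo: pd.DataFrame,
                 volumes: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Inner join of visits having both an MRI volume row and a CyClo value.

    ``cyclo`` is the (measured + propagated) table of :func:`propagate_cyclo`.
    Returns the matched analysis table and a report of counts before/after
    propagation.
    """
    mri = volumes.index
    measured = cyclo.index[cyclo["source"] == "measured"]
    both_raw = mri.intersection(measured)
    both = mri.intersection(cyclo.index)
    if len(both) == 0:
        raise ConfigError("no visit has both an MRI volume and a CyClo value")
    matched = visits.loc[both].join(cyclo.loc[both, ["cyclo", "source", "gap"]])
    matched = matched.join(volumes.loc[both])
    report = {"n_mri": int(len(mri)), "n_cyclo": int(len(cyclo)),
              "n_matched_same_visit": int(len(both_raw)),
              "n_matched_after_propagation": int(len(both))}
    return matched, report


def run_pipeline(config: PipelineConfig, out_dir: Path | str) -> Path:
    """Execute all stages in order; returns the run directory."""
    config.validate()
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("cytoclock")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "config"
    try:
        config.to_yaml(run_dir / "config.yaml")

        stage = "simulate"
        sim = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "simulate"))
        visits, panel, volumes, truth = generate_cohort(sim)
        dup_rng = np.random.default_rng(stage_seed(config.seed, "duplicates"))
        dups = inject_duplicate_noise(panel, sim.duplicate_cv_sd, rng=dup_rng)
        io.write_table(visits, run_dir / "visits.tsv")
        io.write_table(volumes, run_dir / "volumes.tsv")
        io.write_table(dups.rep1, run_dir / "panel_rep1.tsv")
        io.write_table(dups.rep2, run_dir / "panel_rep2.tsv")
        (run_dir / "truth.json").write_text(truth.to_json(), encoding="utf-8")
        log.info("simulate: %d subjects, %d visits (%.1fs)",
                 sim.n_subjects, len(visits), time.time() - t0)

        stage = "preprocess"
        raw = collapse_duplicates_cv_filter(dups, config.cv_threshold)
        miss_rng = np.random.default_rng(stage_seed(config.seed, "missingness"))
        raw = inject_missingness(raw, sim, visits=visits, rng=miss_rng)
        logged = log_transform(raw)
        logged, dropped = drop_high_missingness_markers(logged, config.missing_threshold)
        covs = pd.DataFrame({"age": visits["age"], "sex": visits["sex"]})
        clean = remove_batch_effects(logged, visits["batch"], covs)
        weights = compute_balancing_weights(visits["age"], config.bin_width)
        io.write_table(clean.values, run_dir / "panel_clean.tsv")
        io.write_table(clean.missing_fraction().to_frame("missing_fraction"),
                       run_dir / "missingness_report.tsv", index_label="marker")
        log.info("preprocess: dropped %s; mean missing %.3f (%.1fs)",
                 dropped, clean.missing_fraction().mean(), time.time() - t0)

        stage = "impute"
        spec = ImputationSpec(n_imputations=config.m_imputations,
                              n_sweeps=config.n_sweeps, n_donors=config.n_donors,
                              seed=stage_seed(config.seed, "impute"))
        ensemble = generate_ensemble(clean, spec, weights, sex=visits["sex"])
        imp_dir = run_dir / "imputations"
        imp_dir.mkdir(exist_ok=True)
        for i, pnl in enumerate(ensemble.panels):
            io.write_table(pnl, imp_dir / f"imputation_{i:03d}.tsv")
        io.write_json({"seed": spec.seed, "m": spec.n_imputations,
                       "sweeps": spec.n_sweeps, "donors": spec.n_donors},
                      imp_dir / "manifest.json")
        log.info("impute: M=%d (%.1fs)", ensemble.m, time.time() - t0)

        stage = "clock"
        pooled = fit_clock_ensemble(ensemble, visits["age"], weights,
                                    visits["subject_id"], n_folds=config.n_folds,
                                    rule=config.lambda_rule, pool=config.pool,
                                    seed=stage_seed(config.seed, "clock"))
        cyclo_table = propagate_cyclo(pooled.cyclo, visits, config.max_gap)
        io.write_json({"mean_beta": pooled.mean_beta, "se_beta": pooled.se_beta,
                       "selection_frequency": pooled.selection_frequency,
                       "lambdas": pooled.lambdas, "rule": pooled.rule,
                       "pool": pooled.pool_statistic},
                      run_dir / "clock.json")
        io.write_table(cyclo_table, run_dir / "cyclo.tsv")
        log.info("clock: pooled over %d models (%.1fs)", ensemble.m,
                 time.time() - t0)

        stage = "volumetrics"
        normed = normalize_to_tiv(volumes)
        matched, match_report = match_visits(visits, cyclo_table, normed)
        corr_vars = pd.DataFrame({
            "age": matched["age"], "cyclo": matched["cyclo"],
            "sex": matched["sex"],
            **{k: matched[f"{k}_frac"] for k in NETWORKS}})
        corr, corr_p = correlation_matrix(corr_vars)
        io.write_table(corr, run_dir / "correlation_matrix.tsv", index_label="variable")
        io.write_json({"p_values": corr_p}, run_dir / "correlation_pvalues.json")

        stage = "lmm"
        ladder_data = matched.rename(columns={"GMV_frac": "gmv_frac"})
        ladder = build_model_ladder(ladder_data, response="gmv_frac")
        io.write_table(ladder.table(), run_dir / "ladder.tsv", index_label="row")
        ladder_doc = {
            "models": [{"formula": f.formula, "loglik": f.loglik, "aic": f.aic,
                        "bic": f.bic, "k": f.kparams, "n": f.n_obs,
                        "sigma_u2": f.sigma_u2, "sigma2": f.sigma2}
                       for f in ladder.fits],
            "lrt": [{"chi2": c, "df": d, "p": p} for c, d, p in ladder.lrt],
        }
        io.write_json(ladder_doc, run_dir / "ladder.json")

        stage = "cca"
        X = corr_vars[["age", "cyclo", "sex"]]
        Y = corr_vars[NETWORKS]
        res = fit_cca(X, Y)
        n = len(X)
        bart = bartlett_sequential_test(res.correlations, n, X.shape[1], Y.shape[1])
        rao = rao_f_test(res.correlations, n, X.shape[1], Y.shape[1])
        red = redundancy(res)
        cca_doc = {
            "correlations": res.correlations, "roots": res.roots,
            "x_weights": res.x_weights, "y_weights": res.y_weights,
            "x_loadings": res.x_loadings, "y_loadings": res.y_loadings,
            "bartlett": bart.table, "rao": rao.table,
            "redundancy": {"per_dimension": red.per_dimension,
                           "total_x_given_y": red.total_x_given_y,
                           "total_y_given_x": red.total_y_given_x},
            "n": n,
        }
        io.write_json(cca_doc, run_dir / "cca.json")
        (run_dir / "cca_report.txt").write_text(
            format_cca_report(res, bart, red), encoding="utf-8")

        stage = "summary"
        aics = [f.aic for f in ladder.fits]
        bics = [f.bic for f in ladder.fits]
        summary = {
            "seed": config.seed,
            "n_subjects": sim.n_subjects,
            "n_visits": len(visits),
            "match_report": match_report,
            "selection_frequency": pooled.selection_frequency,
            "cyclo_age_correlation": float(np.corrcoef(
                matched["cyclo"], matched["age"])[0, 1]),
            "ladder_aic": aics, "ladder_bic": bics,
            "best_model_aic": int(np.argmin(aics) + 1),
            "best_model_bic": int(np.argmin(bics) + 1),
            "lrt_model3_vs_model4_p": ladder.lrt[-1][2],
            "canonical_correlations": res.correlations,
            "canonical_roots": res.roots,
            "bartlett_df": [int(d) for d in bart.table["df"]],
            "redundancy_x_given_y": red.total_x_given_y,
            "redundancy_y_given_x": red.total_y_given_x,
        }
        io.write_json(summary, run_dir / "summary.json")
        io.write_manifest(run_dir, extra={"seed": config.seed})
    except Exception:
        log.exception("pipeline aborted at stage %r", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return run_dir


def format_cca_report(res, bart, red) -> str:
    """Human-readable per-function report (weights, loadings, rho, tests)."""
    lines = []
    for k, f in enumerate(res.u_scores.columns):
        rho = res.correlations[k]
        row = bart.table.iloc[k]
        lines.append(f"Canonical function {k + 1}: rho = {rho:.3f}, "
                     f"rho^2 = {rho * rho:.3f}, "
                     f"chi2({int(row['df'])}) = {row['chi2']:.2f}, "
                     f"p = {row['p']:.4g}")
        lines.append("  X side (weight / loading):")
        for v in res.x_weights.index:
            lines.append(f"    {v:<18} {res.x_weights.loc[v, f]:+8.3f}  "
                         f"{res.x_loadings.loc[v, f]:+8.3f}")
        lines.append("  Y side (weight / loading):")
        for v in res.y_weights.index:
            lines.append(f"    {v:<18} {res.y_weights.loc[v, f]:+8.3f}  "
                         f"{res.y_loadings.loc[v, f]:+8.3f}")
        lines.append("")
    lines.append(f"Total redundancy X|Y = {red.total_x_given_y:.3f}, "
                 f"Y|X = {red.total_y_given_x:.3f}")
    return "\n".join(lines) + "\n"
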