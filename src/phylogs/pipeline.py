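"""End-to-end analysis pipeline.

Order of stages, mirroring a genus-scale genome-size study:

1. karyotype summarization (arm measurements -> HCL, AsK%, CV_CI, CV_CL);
2. flow-cytometry genome-size estimation (if histograms are provided),
   filling 2C/1Cx where the trait table lacks them;
3. tree/trait reconciliation (single source of truth for the analysis set);
4. Pagel's-lambda phylogenetic signal on the monoploid genome size (1Cx);
5. PGLS of 1Cx on each karyotype and environmental predictor under BM and
   OU, with AIC ranking per predictor;
6. ANOVA + Tukey-HSD homogeneous-group letters by region and by section.

Each stage writes one TSV into the output directory; a run log records the
seed, package version, dropped species and stage outcomes.  A stage failure
aborts the run with a stage-named error; outputs of earlier stages are left
in place and the log marks the run as failed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .flowcyto import FlowHistogram, detect_g1_peaks, estimate_2c, qc_genome_size
from .groups import GroupStatsError, compare_groups
from .karyotype import read_karyotype_table, summarize_karyotype, write_metrics_table
from .pgls import compare_models, pgls_bm, pgls_ou
from .phylosignal import estimate_lambda
from .tree import Phylogeny, align_tree_and_table, bm_covariance, parse_newick

logger = logging.getLogger(__name__)

DEFAULT_PREDICTORS = (
    "HCL",
    "AsK_pct",
    "CV_CI",
    "CV_CL",
    "elevation_m",
    "annual_mean_temp_c",
    "annual_precip_mm",
)

MIN_SPECIES_PGLS = 5


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """Inputs, toggles and output location for one pipeline run."""

    tree_path: str | Path
    traits_path: str | Path
    out_dir: str | Path
    karyotypes_path: str | Path | None = None
    histograms_dir: str | Path | None = None
    response: str = "one_cx_pg"
    predictors: tuple = DEFAULT_PREDICTORS
    models: tuple = ("BM", "OU")
    alpha_level: float = 0.05
    standard_2c_pg: float = 30.9
    group_columns: tuple = ("region", "section")
    holm_correction: bool = False
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        for name in ("tree_path", "traits_path"):
            if not Path(getattr(self, name)).exists():
                problems.append(f"{name} does not exist: {getattr(self, name)}")
        for name in ("karyotypes_path", "histograms_dir"):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                problems.append(f"{name} does not exist: {val}")
        return problems


def validate_inputs(config: PipelineConfig) -> dict:
    """Schema and consistency checks on the configured input files.

    Returns a report dict with per-file problem lists; an empty ``problems``
    list means the inputs look analyzable.
    """
    report: dict = {"problems": list(config.validate()), "dropped": []}
    if report["problems"]:
        return report

    traits = pd.read_csv(config.traits_path, sep="\t")
    if "species" not in traits.columns:
        report["problems"].append("traits table lacks a 'species' column")
        return report
    if traits["species"].duplicated().any():
        report["problems"].append("duplicated species in traits table")
    if {"x", "ploidy", "two_n"} <= set(traits.columns):
        bad = traits[traits["two_n"] != traits["x"] * traits["ploidy"]]
        for sp in bad["species"]:
            report["problems"].append(f"{sp}: two_n != x * ploidy")
    if {"two_c_pg", "one_cx_pg", "ploidy"} <= set(traits.columns):
        ok = traits.dropna(subset=["two_c_pg", "one_cx_pg"])
        bad = ok[
            ~np.isclose(ok["one_cx_pg"], ok["two_c_pg"] / ok["ploidy"], rtol=1e-3)
        ]
        for sp in bad["species"]:
            report["problems"].append(f"{sp}: one_cx_pg != two_c_pg / ploidy")

    try:
        tree = parse_newick(Path(config.tree_path).read_text())
    except Exception as exc:
        report["problems"].append(f"tree: {exc}")
        return report
    tips = set(tree.tip_labels)
    table_sp = set(traits["species"])
    report["tree_only"] = sorted(tips - table_sp)
    report["table_only"] = sorted(table_sp - tips)
    if not tips & table_sp:
        report["problems"].append("tree tips and trait species do not overlap")
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of per-stage result tables."""
    problems = config.validate()
    if problems:
        raise PipelineError("validate", "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"phylogs {__version__}",
        f"seed {config.seed}",
    ]
    results: dict = {}

    def fail(stage: str, exc: Exception):
        log_lines.append(f"FAILED at stage {stage}: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise PipelineError(stage, str(exc)) from exc

    traits = pd.read_csv(config.traits_path, sep="\t")

    # -- stage: karyotype ------------------------------------------------
    if config.karyotypes_path is not None:
        try:
            karyos = read_karyotype_table(config.karyotypes_path)
            metrics = [summarize_karyotype(k) for k in karyos.values()]
            results["karyotype"] = write_metrics_table(
                metrics, out / "karyotype_metrics.tsv"
            )
            log_lines.append(f"karyotype: {len(metrics)} species summarized")
            # fill metric columns absent from the trait table
            kdf = results["karyotype"].set_index("species")
            for col in ("HCL", "AsK_pct", "CV_CI", "CV_CL"):
                if col not in traits.columns:
                    traits[col] = traits["species"].map(kdf[col])
        except Exception as exc:
            fail("karyotype", exc)

    # -- stage: genome size ----------------------------------------------
    if config.histograms_dir is not None:
        try:
            gs_rows = _genome_size_stage(config)
            results["genome_size"] = gs_rows
            gs_rows.to_csv(out / "genome_size.tsv", sep="\t", index=False)
            log_lines.append(f"genome_size: {len(gs_rows)} species estimated")
            gmap = gs_rows.set_index("species")
            if "two_c_pg" not in traits.columns:
                traits["two_c_pg"] = np.nan
            missing = traits["two_c_pg"].isna()
            traits.loc[missing, "two_c_pg"] = traits.loc[
                missing, "species"
            ].map(gmap["two_c_pg"])
        except Exception as exc:
            fail("genome_size", exc)

    if "ploidy" not in traits.columns:
        traits["ploidy"] = 2
    if "one_cx_pg" not in traits.columns or traits["one_cx_pg"].isna().any():
        traits["one_cx_pg"] = traits["two_c_pg"] / traits["ploidy"]
    traits.to_csv(out / "trait_table.tsv", sep="\t", index=False)

    # -- stage: alignment -------------------------------------------------
    try:
        tree = parse_newick(Path(config.tree_path).read_text())
        needed = [config.response] + [
            p for p in config.predictors if p in traits.columns
        ]
        pruned, table = align_tree_and_table(
            tree, traits, needed, species_col="species"
        )
        dropped = sorted(set(tree.tip_labels) - set(pruned.tip_labels))
        log_lines.append(
            f"alignment: {pruned.n_tips} species analyzed, dropped: "
            + (",".join(dropped) if dropped else "none")
        )
        results["analysis_species"] = list(pruned.tip_labels)
    except Exception as exc:
        fail("alignment", exc)

    # -- stage: phylogenetic signal ---------------------------------------
    try:
        C = bm_covariance(pruned)
        y = table[config.response].to_numpy(dtype=float)
        sig = estimate_lambda(y, C)
        results["signal"] = pd.DataFrame(
            [
                {
                    "trait": config.response,
                    "lambda_hat": round(sig.lambda_hat, 6),
                    "loglik_hat": round(sig.loglik_at_hat, 6),
                    "loglik0": round(sig.loglik_at_zero, 6),
                    "LRT": round(sig.lrt_stat, 6),
                    "p": sig.p_value,
                    "n": sig.n_species,
                }
            ]
        )
        results["signal"].to_csv(out / "signal.tsv", sep="\t", index=False)
        log_lines.append(
            f"signal: lambda={sig.lambda_hat:.3f} p={sig.p_value:.3g}"
        )
    except Exception as exc:
        fail("signal", exc)

    # -- stage: PGLS -------------------------------------------------------
    try:
        if pruned.n_tips < MIN_SPECIES_PGLS:
            raise ValueError(
                f"n too small: {pruned.n_tips} species < {MIN_SPECIES_PGLS}"
            )
        rows = []
        fits_by_predictor: dict = {}
        for pred in config.predictors:
            if pred not in table.columns:
                log_lines.append(f"pgls: predictor {pred} absent, skipped")
                continue
            x = table[pred].to_numpy(dtype=float)
            fits = []
            if "BM" in config.models:
                fits.append(
                    pgls_bm(y, x, pruned, response=config.response, predictor=pred)
                )
            if "OU" in config.models:
                fits.append(
                    pgls_ou(y, x, pruned, response=config.response, predictor=pred)
                )
            ranking = compare_models(fits)
            best = ranking["model"].iloc[0]
            fits_by_predictor[pred] = fits
            for f in fits:
                rows.append(
                    {
                        "response": f.response,
                        "predictor": f.predictor,
                        "model": f.model_tag,
                        "intercept": f.intercept,
                        "slope": f.slope,
                        "se_slope": float(f.se_beta[1]),
                        "t": float(f.t_stats[1]),
                        "p": float(f.p_values[1]),
                        "sigma2": f.sigma2_hat,
                        "alpha": f.alpha_hat if f.alpha_hat is not None else "",
                        "loglik": f.loglik,
                        "AIC": f.aic,
                        "delta_AIC": float(
                            ranking.loc[ranking["model"] == f.model_tag, "delta_aic"].iloc[0]
                        ),
                        "best_model": best,
                        "n": f.n,
                        "flags": ";".join(f.flags),
                    }
                )
        pgls_df = pd.DataFrame(rows)
        if config.holm_correction and len(pgls_df):
            pgls_df["p_holm"] = _holm(pgls_df["p"].to_numpy())
        results["pgls"] = pgls_df
        pgls_df.to_csv(out / "pgls.tsv", sep="\t", index=False)
        results["pgls_fits"] = fits_by_predictor
        log_lines.append(f"pgls: {len(pgls_df)} fits over {len(fits_by_predictor)} predictors")
    except Exception as exc:
        fail("pgls", exc)

    # -- stage: group comparison -------------------------------------------
    try:
        for col in config.group_columns:
            if col not in table.columns:
                log_lines.append(f"groups: column {col} absent, skipped")
                continue
            try:
                comp = compare_groups(
                    table[config.response].to_numpy(dtype=float),
                    table[col].astype(str).to_numpy(),
                    alpha=config.alpha_level,
                )
            except GroupStatsError as exc:
                log_lines.append(f"groups[{col}]: skipped ({exc})")
                continue
            summary = pd.DataFrame(
                {
                    "group": comp.group_labels,
                    "n": comp.group_ns,
                    "mean": np.round(comp.group_means, 4),
                    "letter": comp.letters,
                }
            )
            summary.to_csv(out / f"groups_{col}.tsv", sep="\t", index=False)
            comp.pairwise.to_csv(
                out / f"groups_{col}_pairwise.tsv", sep="\t", index=False
            )
            results[f"groups_{col}"] = comp
            log_lines.append(
                f"groups[{col}]: F={comp.anova.F:.3f} p={comp.anova.p:.3g} "
                f"letters={','.join(comp.letters)}"
            )
    except Exception as exc:
        fail("groups", exc)

    log_lines.append("run complete")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return results


def _genome_size_stage(config: PipelineConfig) -> pd.DataFrame:
    """Estimate per-species 2C from histogram CSVs named ``<species>_rep<k>.csv``."""
    hist_dir = Path(config.histograms_dir)
    by_species: dict[str, list[Path]] = {}
    for path in sorted(hist_dir.glob("*.csv")):
        species = path.stem.rsplit("_rep", 1)[0]
        by_species.setdefault(species, []).append(path)
    if not by_species:
        raise FileNotFoundError(f"no histogram CSVs in {hist_dir}")

    rows = []
    for species, paths in by_species.items():
        reps, cvs, nuclei = [], [], []
        for path in paths:
            hist = FlowHistogram.from_csv(path, sample_label=species)
            sample, standard = detect_g1_peaks(hist)
            reps.append(
                estimate_2c(
                    sample.mean_channel,
                    standard.mean_channel,
                    config.standard_2c_pg,
                )
            )
            cvs.extend([sample.cv_percent, standard.cv_percent])
            nuclei.append(sample.nuclei + standard.nuclei)
        est = qc_genome_size(
            species,
            per_individual=[reps],
            nuclei_counts=nuclei,
            peak_cvs=cvs,
        )
        rows.append(
            {
                "species": species,
                "two_c_pg": round(est.two_c_pg, 4),
                "one_cx_pg": round(est.one_cx_pg, 4),
                "n_individuals": est.n_individuals,
                "n_histograms": len(paths),
                "qc_flags": ";".join(est.qc_flags),
            }
        )
    return pd.DataFrame(rows)


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
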