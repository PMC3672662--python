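"""End-to-end orchestration: synthesize -> DE -> MARA -> GSEA -> LDA -> IHC.

A single config (YAML/JSON-shaped dict) enables stages, points each at
real input files or at a simulation block, and fixes one seed.  Every
stage writes its intermediates to the output directory and contributes
a machine-readable entry to the run report.  The report contains no
timestamps or absolute paths, so identical config + seed reproduces it
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix, SiteCountMatrix
from .datasets import illustrative_gene_sets, load_transplant_tables
from .diffexpr import FilterCriteria, apply_filters, moderated_t
from .gsea import permute_and_score, rank_by_difference, read_gmt
from .ihc import MahalanobisSegmenter, fit_color_reference
from .limiting_dilution import (
    DilutionAssay,
    compare_frequencies,
    fit_single_hit,
    goodness_of_fit,
)
from .mara import MotifActivityModel
from .simulate import (
    SimulationConfig,
    simulate_dilution_assay,
    simulate_expression_dataset,
    simulate_ihc_image,
    simulate_motif_dataset,
)

__all__ = ["ConfigError", "load_config", "run_pipeline"]

_STAGE_ORDER = ("lda", "diffexpr", "mara", "gsea", "ihc")


class ConfigError(ValueError):
    """Invalid pipeline configuration (raised before any computation)."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    return cfg


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _sim_config(block: dict, seed: int) -> SimulationConfig:
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(block) - fields
    if unknown:
        raise ConfigError(f"unknown simulation parameters: {sorted(unknown)}")
    merged = {"seed": seed, **block}
    if "image_size" in merged:
        merged["image_size"] = tuple(merged["image_size"])
    return SimulationConfig(**merged)


def _validate(config: dict) -> dict:
    stages = config.get("stages")
    if not isinstance(stages, dict) or not stages:
        raise ConfigError("config needs a non-empty 'stages' mapping")
    unknown = set(stages) - set(_STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    stochastic = False
    for name, block in stages.items():
        if not isinstance(block, dict):
            raise ConfigError(f"stage {name!r} must be a mapping")
        if "simulate" in block:
            stochastic = True
            has_real = any(
                k.endswith(("_tsv", "_csv", "_png")) or k == "fixture" for k in block
            )
            if has_real:
                raise ConfigError(
                    f"stage {name!r}: give real inputs or a simulate block, not both"
                )
        if name == "gsea" and not any(
            k in block for k in ("gene_sets", "gene_sets_gmt")
        ):
            raise ConfigError("gsea stage enabled without 'gene_sets' or 'gene_sets_gmt'")
        if name in ("diffexpr", "mara") and "simulate" not in block and \
                "expression_tsv" not in block:
            raise ConfigError(f"stage {name!r} needs 'expression_tsv' or 'simulate'")
    if (stochastic or "gsea" in stages) and "seed" not in config:
        raise ConfigError("a seed is mandatory when any stochastic stage is enabled")
    return stages


def _stage_lda(block: dict, seed: int, outdir: Path) -> dict:
    if "fixture" in block:
        if block["fixture"] != "transplant_tables":
            raise ConfigError(f"unknown LDA fixture {block['fixture']!r}")
        assays = load_transplant_tables()
    elif "csv" in block:
        assays = DilutionAssay.from_csv(block["csv"])
    elif "simulate" in block:
        sim = block["simulate"]
        assays = {}
        for i, group in enumerate(sim.get("groups", ["simulated"])):
            assays[group] = simulate_dilution_assay(
                frequency=float(sim["frequency"]),
                doses=sim["doses"],
                n_per_dose=sim["n_per_dose"],
                seed=seed + i,
                group_label=group,
            )
    else:
        raise ConfigError("lda stage needs 'fixture', 'csv' or 'simulate'")

    estimates, rows = {}, []
    for label, assay in assays.items():
        est = fit_single_hit(assay)
        entry = {
            "boundary": est.boundary_flag,
            "log_likelihood": est.log_likelihood,
        }
        if est.boundary_flag == "none":
            gof = goodness_of_fit(assay, est)
            entry.update(
                frequency=est.f_hat,
                denominator=est.denominator,
                ci_denominators=[round(1 / est.ci_low), round(1 / est.ci_high)],
                gof_p=round(gof.p_value, 6),
            )
        estimates[label] = entry
        rows.append({"group": label, **entry})
    pd.DataFrame(rows).to_csv(outdir / "lda_estimates.tsv", sep="\t", index=False)

    comparisons = {}
    labels = list(assays)
    # paired virgin/parous groups share a trailing variant tag; otherwise all pairs
    suffixes = {}
    for lab in labels:
        suffixes.setdefault(lab.rsplit("_", 1)[-1], []).append(lab)
    pairs = [tuple(v) for v in suffixes.values() if len(v) == 2]
    if not pairs:
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    for a, b in pairs:
        cmp = compare_frequencies(assays[a], assays[b])
        comparisons[f"{a}_vs_{b}"] = {
            "chi2": round(cmp.chi2, 6),
            "p_value": float(f"{cmp.p_value:.6g}"),
        }
    return {"estimates": estimates, "comparisons": comparisons}


def _load_expression(block: dict, seed: int, outdir: Path):
    if "simulate" in block:
        expr, truth = simulate_expression_dataset(_sim_config(block["simulate"], seed))
        expr.to_tsv(outdir / "expression.tsv", outdir / "samples.csv")
        return expr, truth
    expr = ExpressionMatrix.from_tsv(block["expression_tsv"], block["sample_sheet_csv"])
    return expr, None


def _stage_diffexpr(block: dict, seed: int, outdir: Path) -> dict:
    expr, _ = _load_expression(block, seed, outdir)
    result = moderated_t(expr)
    crit = FilterCriteria(**block.get("filters", {}))
    passing = apply_filters(result, crit)
    result.assign(passes_filters=result.index.isin(passing)).to_csv(
        outdir / "de_table.tsv", sep="\t", index_label="gene"
    )
    return {
        "n_genes": int(result.shape[0]),
        "n_pass": len(passing),
        "filters": dataclasses.asdict(crit),
    }


def _stage_mara(block: dict, seed: int, outdir: Path) -> dict:
    if "simulate" in block:
        sim = dict(block["simulate"])
        planted = sim.pop("planted_activity_changes", {})
        expr, sites, _ = simulate_motif_dataset(_sim_config(sim, seed), planted)
    else:
        expr = ExpressionMatrix.from_tsv(block["expression_tsv"], block["sample_sheet_csv"])
        sites = SiteCountMatrix.from_tsv(block["site_counts_tsv"])
    model = MotifActivityModel(ridge_lambda=block.get("ridge_lambda", "cv")).fit(expr, sites)
    model.activities_.to_csv(outdir / "motif_activities.tsv", sep="\t", index_label="motif")
    report = model.change_report()
    report.to_csv(outdir / "motif_changes.tsv", sep="\t", index_label="motif")
    top = report.head(5)
    return {
        "lambda": model.lambda_,
        "n_shared_genes": model.n_shared_genes_,
        "top_motifs": {m: round(float(z), 4) for m, z in top["z"].items()},
    }


def _stage_gsea(block: dict, seed: int, outdir: Path) -> dict:
    if "simulate" in block:
        expr, _ = simulate_expression_dataset(_sim_config(block["simulate"], seed))
    else:
        expr = ExpressionMatrix.from_tsv(block["expression_tsv"], block["sample_sheet_csv"])
    ranked = rank_by_difference(
        expr.condition_frame("parous"), expr.condition_frame("virgin")
    )
    if block.get("gene_sets") == "illustrative":
        sets = illustrative_gene_sets()
    elif "gene_sets_gmt" in block:
        sets = read_gmt(block["gene_sets_gmt"])
    elif "gene_sets" in block and isinstance(block["gene_sets"], dict):
        sets = block["gene_sets"]
    else:
        raise ConfigError("gsea stage needs gene_sets or gene_sets_gmt")
    results = permute_and_score(
        ranked, sets, n_perm=int(block.get("n_perm", 1000)), seed=seed
    )
    results.to_csv(outdir / "gsea_results.tsv", sep="\t")
    return {
        set_name: {
            "es": round(float(row.es), 4),
            "nes": round(float(row.nes), 4),
            "p_nominal": float(row.p_nominal),
            "fdr_q": round(float(row.fdr_q), 4),
        }
        for set_name, row in results.iterrows()
    }


def _stage_ihc(block: dict, seed: int, outdir: Path) -> dict:
    quantile = float(block.get("quantile", 0.99))
    if "simulate" in block:
        cfg = _sim_config(block["simulate"], seed)
        image, truth_mask = simulate_ihc_image(cfg)
        ref_pixels = image[truth_mask][:2000].astype(float)
        from PIL import Image

        Image.fromarray(image).save(outdir / "ihc_synthetic.png")
    else:
        from PIL import Image

        image = np.asarray(Image.open(block["image_png"]).convert("RGB"))
        ref_pixels = pd.read_csv(block["training_pixels_csv"]).to_numpy(float)
    seg = MahalanobisSegmenter(quantile=quantile).fit(
        fit_color_reference(ref_pixels)
    ).segment(image)
    return {
        "positive_fraction": round(seg.positive_fraction, 4),
        "threshold_d2": round(seg.threshold_used, 4),
    }


_RUNNERS = {
    "lda": _stage_lda,
    "diffexpr": _stage_diffexpr,
    "mara": _stage_mara,
    "gsea": _stage_gsea,
    "ihc": _stage_ihc,
}


def run_pipeline(config: dict, output_dir) -> dict:
    """Validate, run enabled stages in order, write and return the report."""
    stages = _validate(config)
    seed = int(config.get("seed", 0))
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package": "parityomics",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": {},
    }
    for name in _STAGE_ORDER:
        if name not in stages:
            continue
        try:
            report["stages"][name] = _RUNNERS[name](stages[name], seed, outdir)
        except ConfigError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
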