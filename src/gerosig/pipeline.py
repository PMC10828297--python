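"""End-to-end orchestration: simulate -> DEGs -> correlate -> converge ->
enrich -> score -> single-cell filter -> clock.

A run consumes a dataset directory (context manifest plus gene sets,
aging reference, marker fixture and clock inputs — either real exports or
the output of :func:`gerosig.synthetic.write_dataset`) and a
:class:`RunConfig`, and writes every stage's tabular output plus a
machine-readable ``summary.json`` and provenance record.  All stage
outputs are pure functions of (inputs, config, seed), so a rerun with the
same seed reproduces the output tree byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, ambient, convergence, enrichment, synthetic
from . import clock as clockmod
from .correlation import CorrelationMatrix, block_summary, correlation_matrix
from .sig_io import (ContextKey, DEGThresholds, GerosigError, SignatureTable,
                     SignedGeneList, read_gene_list, read_gmt, read_tables,
                     select_degs)

logger = logging.getLogger("gerosig")


class ConfigError(GerosigError):
    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class RunConfig:
    """All tunable analysis parameters, defaulting to the published rules."""

    min_abs_fc: float = 1.25
    max_fdr: float = 0.05
    min_shared: int = 10
    alpha: float = 0.05
    min_contexts: dict = field(
        default_factory=lambda: dict(convergence.DEFAULT_MIN_CONTEXTS))
    ypar_min_contexts: int = 3
    k_shared: int = 3
    ora_min_overlap: int = 2
    ora_p_cutoff: float = 0.01
    ora_min_enrichment: float = 1.5
    score_fdr_cutoff: float = 0.01
    weight_organ: float = 1.0
    weight_parabiosis_celltype: float = 0.5
    sc_top_markers: int = 5
    sc_top_expressed: int = 50
    sc_min_frac: float = 0.01
    sc_min_cells: int = 5
    sc_min_umi: int = 1
    clock_scale: str = "zscore"
    clock_collision_policy: str = "sum"
    seed: int = 0

    @property
    def thresholds(self) -> DEGThresholds:
        return DEGThresholds(self.min_abs_fc, self.max_fdr)

    @property
    def score_weights(self) -> dict:
        return {"bulk": self.weight_organ,
                "single_cell": self.weight_parabiosis_celltype}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_CONFIG_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def config_from_dict(raw: Mapping) -> RunConfig:
    """Build a validated RunConfig; unknown keys and bad values are all
    reported together."""
    errors = [f"unknown config key {k!r}" for k in raw
              if k not in _CONFIG_FIELDS]
    kwargs = {k: v for k, v in raw.items() if k in _CONFIG_FIELDS}
    cfg = RunConfig(**kwargs)
    if not cfg.min_abs_fc > 1:
        errors.append("min_abs_fc must exceed 1")
    for name in ("max_fdr", "alpha", "ora_p_cutoff", "score_fdr_cutoff"):
        v = getattr(cfg, name)
        if not 0 < v < 1:
            errors.append(f"{name} must lie in (0, 1)")
    for name in ("min_shared", "k_shared", "ora_min_overlap",
                 "ypar_min_contexts", "sc_top_markers", "sc_top_expressed"):
        if getattr(cfg, name) < 1:
            errors.append(f"{name} must be >= 1")
    if any(v < 1 for v in cfg.min_contexts.values()):
        errors.append("min_contexts values must be >= 1")
    if cfg.clock_scale not in ("zscore", "minmax", "none"):
        errors.append("clock_scale must be zscore/minmax/none")
    if cfg.clock_collision_policy not in ("sum", "max", "error"):
        errors.append("clock_collision_policy must be sum/max/error")
    if errors:
        raise ConfigError(errors)
    return cfg


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config file (missing keys take defaults)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config file must hold a mapping"])
    return config_from_dict(raw)


# ---------------------------------------------------------------------------
# stage helpers (shared by run_pipeline, the CLI and the test experiments)
# ---------------------------------------------------------------------------

def split_by_role(tables: Mapping[ContextKey, SignatureTable]
                  ) -> dict[str, list[SignatureTable]]:
    out: dict[str, list[SignatureTable]] = {}
    for ctx, t in tables.items():
        out.setdefault(ctx.role, []).append(t)
    return out


def build_trend_memberships(
    tables: Mapping[ContextKey, SignatureTable],
    aging_list: SignedGeneList,
    cfg: RunConfig,
) -> pd.DataFrame:
    """Both trends' six-set memberships from a full table collection."""
    thr = cfg.thresholds
    roles = split_by_role(tables)
    gi_tables: dict[str, list[SignatureTable]] = {}
    for t in roles.get("GI", []):
        gi_tables.setdefault(t.context.intervention, []).append(t)
    frames = []
    for trend, gi_dir, ypar_dir in (("gi_down_aging_up", "down", "up"),
                                    ("gi_up_aging_down", "up", "down")):
        gi_sets = {}
        for name, tabs in sorted(gi_tables.items()):
            rule = convergence.InterventionRule(
                name, cfg.min_contexts.get(name, 1), gi_dir)
            gi_sets[name] = convergence.intervention_deg_set(tabs, rule, thr)
        ypar = convergence.ypar_deg_set(
            roles.get("YPAR", []), ypar_dir, thr, cfg.ypar_min_contexts)
        frames.append(convergence.trend_intersection(
            gi_sets, ypar, aging_list, trend))
    return pd.concat(frames)


def run_enrichment(
    tables: Mapping[ContextKey, SignatureTable],
    library,
    cfg: RunConfig,
) -> dict[tuple[ContextKey, str], pd.DataFrame]:
    """ORA per (context, direction), background restricted to measured genes."""
    thr = cfg.thresholds
    out = {}
    for ctx, t in tables.items():
        lib = library.restricted_to(t.genes)
        for direction in ("up", "down"):
            degs = select_degs(t, thr, direction).index
            out[(ctx, direction)] = enrichment.ora_test(
                degs, lib, cfg.ora_min_overlap, cfg.ora_p_cutoff,
                cfg.ora_min_enrichment)
    return out


def trend_rank_scores(
    results: Mapping[tuple[ContextKey, str], pd.DataFrame],
    cfg: RunConfig,
) -> dict[str, pd.Series]:
    """The four trend score tables feeding the rank-score correlations.

    ``aging_up``/``aging_down``: enrichment hits of the aging reference
    contexts' up/down DEG lists.  ``gi_down``/``gi_up``: hits of the
    interventions' down/up lists pooled with the young parabiont's
    opposite-direction lists (which recapitulate aging).
    """
    def pick(role_dirs: list[tuple[str, str]]) -> dict[ContextKey, pd.DataFrame]:
        sel = {}
        for (ctx, direction), df in results.items():
            if (ctx.role, direction) in role_dirs:
                sel[ctx] = df
        return sel

    scores = {}
    scores["aging_up"] = enrichment.pathway_rank_scores(
        pick([("AGING", "up")]), cfg.score_fdr_cutoff, cfg.score_weights)
    scores["aging_down"] = enrichment.pathway_rank_scores(
        pick([("AGING", "down")]), cfg.score_fdr_cutoff, cfg.score_weights)
    scores["gi_down"] = enrichment.pathway_rank_scores(
        pick([("GI", "down"), ("YPAR", "up")]), cfg.score_fdr_cutoff,
        cfg.score_weights)
    scores["gi_up"] = enrichment.pathway_rank_scores(
        pick([("GI", "up"), ("YPAR", "down")]), cfg.score_fdr_cutoff,
        cfg.score_weights)
    return scores


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)


def run_pipeline(data_dir: str | Path, outdir: str | Path,
                 cfg: RunConfig | None = None) -> dict:
    """Run every stage on a dataset directory; returns the summary dict.

    Expects the file layout written by :func:`gerosig.synthetic.write_dataset`
    (``manifest.tsv``, ``genesets.gmt``, ``aging_genes.tsv``, marker/counts
    fixture, clock inputs, optional ``truth.json`` enabling recovery
    metrics).  Raises before any computation if a required input is absent.
    """
    cfg = cfg or RunConfig()
    data_dir, outdir = Path(data_dir), Path(outdir)
    required = ["manifest.tsv", "genesets.gmt", "aging_genes.tsv",
                "markers.tsv", "sc_counts.tsv", "sc_degs.tsv",
                "clock_model.tsv", "clock_expression.tsv",
                "clock_samples.tsv", "homolog_map.tsv", "gene_lengths.tsv"]
    missing = [f for f in required if not (data_dir / f).exists()]
    if missing:
        raise GerosigError(f"missing input file(s): {missing}")
    outdir.mkdir(parents=True, exist_ok=True)
    thr = cfg.thresholds
    summary: dict = {}

    tables = read_tables(data_dir / "manifest.tsv")
    if not tables:
        raise GerosigError("manifest lists no contexts")
    logger.info("loaded %d signature tables", len(tables))

    # --- DEG selection audit ------------------------------------------------
    deg_rows = []
    for ctx, t in tables.items():
        s = select_degs(t, thr, "both")
        deg_rows.append((ctx.label, ctx.role, ctx.modality,
                         int((s > 0).sum()), int((s < 0).sum())))
    degs_df = pd.DataFrame(
        deg_rows, columns=["context", "role", "modality", "n_up", "n_down"])
    _write(degs_df, outdir / "degs_summary.tsv", index=False)
    summary["n_contexts"] = len(tables)
    summary["total_degs"] = int((degs_df["n_up"] + degs_df["n_down"]).sum())

    # --- correlation --------------------------------------------------------
    corr_tables = [t for t in tables.values() if t.context.role != "CI"]
    matrix = correlation_matrix(corr_tables, thr, cfg.min_shared, cfg.alpha)
    _write(matrix.to_pairs(), outdir / "correlation_pairs.tsv", index=False)
    _write(matrix.rho, outdir / "correlation_matrix.tsv")
    blocks = block_summary(matrix, "role")
    _write(blocks, outdir / "correlation_blocks.tsv", index=False)
    for _, row in blocks.iterrows():
        key = f"corr_{row['role_a']}x{row['role_b']}"
        summary[key] = {"mean_rho": None if pd.isna(row["mean_rho"])
                        else round(float(row["mean_rho"]), 6),
                        "n_significant": int(row["n_significant"]),
                        "frac_negative": None if pd.isna(row["frac_negative"])
                        else round(float(row["frac_negative"]), 6)}

    # --- convergence --------------------------------------------------------
    aging_list = read_gene_list(data_dir / "aging_genes.tsv")
    memberships = build_trend_memberships(tables, aging_list, cfg)
    _write(memberships, outdir / "memberships.tsv")
    report = convergence.shared_gene_report(
        memberships, cfg.k_shared, list(tables.values()))
    _write(report, outdir / "convergence_report.tsv", index=False)
    _write(convergence.venn_counts(memberships),
           outdir / "venn_counts.tsv", index=False)
    consistency = convergence.direction_consistency_summary(
        [t for t in tables.values() if t.context.role == "CI"], thr)
    _write(consistency.to_frame(), outdir / "direction_consistency.tsv")
    summary["n_shared_genes"] = int(report["gene"].nunique())
    summary["median_direction_consistency"] = (
        round(float(consistency.median()), 6) if len(consistency) else None)

    truth_path = data_dir / "truth.json"
    if truth_path.exists():
        with open(truth_path, encoding="utf-8") as fh:
            truth = json.load(fh)
        planted = set(truth["program_genes"])
        found = set(report["gene"])
        summary["convergence_sensitivity"] = round(
            len(found & planted) / len(planted), 6)
        summary["convergence_fdp"] = round(
            len(found - planted) / len(found), 6) if found else 0.0

    # --- enrichment & rank scores ------------------------------------------
    library = read_gmt(data_dir / "genesets.gmt")
    gi_results = run_enrichment(
        {c: t for c, t in tables.items() if c.role != "CI"}, library, cfg)
    enr_rows = []
    for (ctx, direction), df in gi_results.items():
        df = df.assign(context=ctx.label, direction=direction)
        enr_rows.append(df)
    _write(pd.concat(enr_rows, ignore_index=True),
           outdir / "enrichment.tsv", index=False)
    scores = trend_rank_scores(gi_results, cfg)
    score_long = pd.concat(
        [s.rename("score").to_frame().assign(trend=k).rename_axis("set_id")
         for k, s in scores.items()]).reset_index()
    _write(score_long[["trend", "set_id", "score"]],
           outdir / "rank_scores.tsv", index=False)
    corr_rows = []
    for a, b in (("aging_up", "gi_down"), ("aging_down", "gi_up")):
        try:
            rho, p, n = enrichment.rank_score_correlation(scores[a], scores[b])
        except GerosigError:
            rho, p, n = float("nan"), float("nan"), 0
        corr_rows.append((a, b, rho, p, n))
        summary[f"rank_corr_{a}_vs_{b}"] = {
            "rho": None if np.isnan(rho) else round(rho, 6), "n": n}
    _write(pd.DataFrame(corr_rows,
                        columns=["scores_a", "scores_b", "rho", "pvalue", "n"]),
           outdir / "rank_score_correlations.tsv", index=False)

    # --- chronic-inflammation maps -----------------------------------------
    ci_tables = [t for c, t in tables.items() if c.role == "CI"]
    if ci_tables:
        gene_scores = enrichment.ci_gene_scores(ci_tables, thr)
        highlight = (report.drop_duplicates("gene")
                     .set_index("gene")["trend"])
        gene_overlay = enrichment.overlay_report(gene_scores, highlight)
        _write(gene_overlay, outdir / "ci_gene_scores.tsv")
        ci_results = run_enrichment(
            {t.context: t for t in ci_tables}, library, cfg)
        path_scores = enrichment.ci_pathway_scores(
            ci_results, cfg.score_fdr_cutoff)
        gi_hi = pd.concat([
            scores["gi_down"][scores["gi_down"] > 0].to_frame("s")
            .assign(trend="gi_down"),
            scores["gi_up"][scores["gi_up"] > 0].to_frame("s")
            .assign(trend="gi_up")])
        gi_hi = gi_hi[~gi_hi.index.duplicated()]["trend"]
        path_overlay = enrichment.overlay_report(path_scores, gi_hi)
        _write(path_overlay, outdir / "ci_pathway_scores.tsv")
        hl = gene_overlay[gene_overlay["highlighted"]]
        for trend, grp in hl.groupby("trend"):
            summary[f"ci_mean_score_{trend}"] = {
                "bulk": round(float(grp["bulk_score"].mean()), 6),
                "sc": round(float(grp["sc_score"].mean()), 6),
                "n_genes": int(len(grp))}

    # --- single-cell ambient filter ----------------------------------------
    markers = ambient.read_marker_table(data_dir / "markers.tsv")
    counts = ambient.read_counts(data_dir / "sc_counts.tsv")
    kept_genes = ambient.prefilter_genes(
        counts, cfg.sc_min_frac, cfg.sc_min_cells, cfg.sc_min_umi)
    expr_ranks = ambient.rank_expression(counts.loc[kept_genes])
    sc_degs = pd.read_csv(data_dir / "sc_degs.tsv", sep="\t")
    retained_rows, excluded_frames = [], []
    for ct, grp in sc_degs.groupby("cell_type"):
        retained, excluded = ambient.filter_ambient_degs(
            list(grp["gene"]), ct, markers, expr_ranks,
            cfg.sc_top_markers, cfg.sc_top_expressed)
        retained_rows += [(ct, g) for g in retained]
        excluded_frames.append(excluded.assign(cell_type=ct))
    _write(pd.DataFrame(retained_rows, columns=["cell_type", "gene"]),
           outdir / "ambient_retained.tsv", index=False)
    excluded_all = pd.concat(excluded_frames, ignore_index=True)
    _write(excluded_all, outdir / "ambient_excluded.tsv", index=False)
    summary["sc_genes_prefiltered_out"] = len(counts) - len(kept_genes)
    summary["ambient_degs_excluded"] = int(len(excluded_all))
    if truth_path.exists():
        planted_cont = {(ct, g) for ct, gs in truth["contaminants"].items()
                        for g in gs}
        flagged = {(r["cell_type"], r["gene"])
                   for _, r in excluded_all.iterrows()}
        summary["ambient_filter_exact"] = bool(planted_cont == flagged)

    # --- transcriptomic clock ----------------------------------------------
    model = clockmod.read_clock_model(data_dir / "clock_model.tsv")
    samples = pd.read_csv(data_dir / "clock_samples.tsv", sep="\t",
                          dtype=str).set_index("sample")["group"]
    expr = clockmod.read_expression(
        data_dir / "clock_expression.tsv", data_dir / "gene_lengths.tsv",
        units="counts", groups=samples)
    hmap = clockmod.read_homolog_map(data_dir / "homolog_map.tsv")
    mapped = clockmod.map_homologs(expr, hmap, cfg.clock_collision_policy)
    ages = clockmod.apply_clock(
        clockmod.normalize_for_clock(mapped, model.transform), model)
    scaled = clockmod.scale_ages(ages, cfg.clock_scale)
    ages_df = pd.DataFrame({
        "sample": ages.index, "group": samples.reindex(ages.index),
        "raw_age_years": ages.to_numpy(), "scaled_age": scaled.to_numpy(),
        "panel": "all"})
    _write(ages_df, outdir / "clock_ages.tsv", index=False)
    groups_present = sorted(samples.unique())
    comp_rows = []
    if {"old_control", "gi_treated"} <= set(groups_present):
        delta, p = clockmod.compare_groups(
            ages, samples, order=("old_control", "gi_treated"))
        comp_rows.append(("old_control", "gi_treated", delta, p))
        summary["clock_gi_delta_years"] = round(delta, 6)
        summary["clock_gi_pvalue"] = round(p, 6)
    _write(pd.DataFrame(comp_rows,
                        columns=["reference", "test", "delta_years", "pvalue"]),
           outdir / "clock_comparison.tsv", index=False)

    # --- provenance & summary ----------------------------------------------
    provenance = {"config": cfg.to_dict(), "config_digest": cfg.digest(),
                  "seed": cfg.seed, "gerosig_version": __version__}
    with open(outdir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def run_all(workdir: str | Path, cfg: RunConfig | None = None,
            **simulate_kwargs) -> dict:
    """Simulate a dataset under ``workdir/data`` and run the pipeline into
    ``workdir/results`` with the config's seed."""
    cfg = cfg or RunConfig()
    workdir = Path(workdir)
    synthetic.write_dataset(workdir / "data", seed=cfg.seed,
                            **simulate_kwargs)
    return run_pipeline(workdir / "data", workdir / "results", cfg)


# ---------------------------------------------------------------------------
# in-memory experiment drivers (recovery studies; no file I/O)
# ---------------------------------------------------------------------------

def sign_structure_trial(seed: int, n_genes: int = 1000,
                         n_program: int = 100, noise_sd: float = 0.2,
                         cfg: RunConfig | None = None) -> dict:
    """One seed of the sign-structure recovery study.

    Simulates the GI/YPAR/AGING contexts, computes the shared-DEG
    correlation matrix and the pathway rank-score correlations, and reports
    whether every significant intervention x aging correlation is negative,
    every aging x aging correlation positive, and both trend-score
    correlations positive.
    """
    cfg = cfg or RunConfig()
    truth = synthetic.generate_ground_truth(
        n_genes, n_program, seed=seed, noise_sd=noise_sd)
    contexts = [c for c in synthetic.default_contexts() if c.role != "CI"]
    tables = synthetic.simulate_all_signatures(truth, contexts)
    matrix = correlation_matrix(list(tables.values()), cfg.thresholds,
                                cfg.min_shared, cfg.alpha)
    out = {"seed": seed}
    for pair, key in ((("AGING", "GI"), "gi_aging"),
                      (("AGING", "AGING"), "aging_aging")):
        rhos = []
        k = len(matrix.contexts)
        for i in range(k):
            for j in range(i + 1, k):
                roles = tuple(sorted((matrix.contexts[i].role,
                                      matrix.contexts[j].role)))
                if roles == pair and matrix.mask.iat[i, j]:
                    rhos.append(matrix.rho.iat[i, j])
        out[f"n_sig_{key}"] = len(rhos)
        out[f"all_negative_{key}"] = bool(rhos) and all(r < 0 for r in rhos)
        out[f"all_positive_{key}"] = bool(rhos) and all(r > 0 for r in rhos)
        out[f"mean_rho_{key}"] = float(np.mean(rhos)) if rhos else float("nan")
    library = synthetic.simulate_gene_sets(truth)
    results = run_enrichment(tables, library, cfg)
    scores = trend_rank_scores(results, cfg)
    for a, b, key in (("aging_up", "gi_down", "up_down"),
                      ("aging_down", "gi_up", "down_up")):
        rho, p, n = enrichment.rank_score_correlation(scores[a], scores[b])
        out[f"rank_corr_{key}"] = rho
        out[f"rank_corr_{key}_positive"] = bool(rho > 0)
    return out


def sign_structure_experiment(seeds: Sequence[int], **kwargs) -> pd.DataFrame:
    return pd.DataFrame([sign_structure_trial(s, **kwargs) for s in seeds])


def convergence_trial(seed: int, n_genes: int = 1000, n_program: int = 100,
                      noise_sd: float = 0.1,
                      cfg: RunConfig | None = None) -> dict:
    """One seed of the convergent-signature recovery study: sensitivity and
    false-discovery proportion of the >=k-set shared-gene report for
    planted program genes."""
    cfg = cfg or RunConfig()
    truth = synthetic.generate_ground_truth(
        n_genes, n_program, seed=seed, noise_sd=noise_sd)
    contexts = [c for c in synthetic.default_contexts()
                if c.role in ("GI", "YPAR")]
    tables = synthetic.simulate_all_signatures(truth, contexts)
    memberships = build_trend_memberships(tables, truth.aging_reference(),
                                          cfg)
    report = convergence.shared_gene_report(memberships, cfg.k_shared)
    found = set(report["gene"])
    planted = set(truth.program_genes)
    return {"seed": seed,
            "sensitivity": len(found & planted) / len(planted),
            "fdp": len(found - planted) / len(found) if found else 0.0,
            "n_found": len(found)}


def convergence_experiment(seeds: Sequence[int], **kwargs) -> pd.DataFrame:
    return pd.DataFrame([convergence_trial(s, **kwargs) for s in seeds])


def clock_trial(seed: int, control_age: float = 70.0, shift: float = -10.0,
                n_per_group: int = 5, noise_sd: float = 0.5) -> dict:
    """One seed of the clock group-comparison study: a geroprotective group
    planted ``shift`` years from controls, recovered through the full
    map -> normalize -> apply -> compare protocol."""
    model = synthetic.make_test_clock(seed=seed)
    ages = [control_age] * n_per_group + [control_age + shift] * n_per_group
    groups = ["old_control"] * n_per_group + ["gi_treated"] * n_per_group
    expr = synthetic.simulate_clock_expression(
        model, ages, noise_sd=noise_sd, seed=seed + 1, groups=groups,
        mouse_symbols=True)
    mapped = clockmod.map_homologs(expr, synthetic.clock_homolog_map(model))
    pred = clockmod.apply_clock(
        clockmod.normalize_for_clock(mapped, model.transform), model)
    delta, p = clockmod.compare_groups(pred, expr.groups,
                                       order=("old_control", "gi_treated"))
    return {"seed": seed, "delta_years": delta, "pvalue": p,
            "significant_negative": bool(delta < 0 and p < 0.05)}


def clock_experiment(seeds: Sequence[int], **kwargs) -> pd.DataFrame:
    return pd.DataFrame([clock_trial(s, **kwargs) for s in seeds])
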