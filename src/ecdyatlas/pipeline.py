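"""End-to-end pipeline: simulate -> DE -> catalog -> association ->
positional -> prediction -> timecourse, with one artifact per stage.

A :class:`Workspace` wraps an output directory: stages write their TSV/JSON
artifacts there and later stages (or separate CLI invocations) reload them,
so the pipeline can be run in one shot or verb by verb.  All stochastic
stages draw seeds derived from the single top-level seed.
"""

from __future__ import annotations

import json
import os
import platform
import time
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .association import (isoform_fraction, isoform_response_scan,
                          rgc_correlation_scan, residualize_and_rescan)
from .catalog import (call_responsive, fisher_combine, jaccard_cluster,
                      summarize_catalog, ResponseCatalog)
from .config import SimulationConfig, derive_seed
from .countio import CountMatrix, load_counts, load_sample_sheet
from .diffexpr import (estimate_size_factors, fit_dispersions,
                       normalized_counts, run_de_all_lines, test_exon_de)
from .genome import GeneAnnotation, load_annotation
from .motifs import read_meme
from .positional import (build_neighbor_records, build_profiles,
                         motif_enrichment, proximity_enrichment,
                         select_tss_map)
from .prediction import (build_features, build_matched_sets,
                         calibrate_motif_threshold, loco_evaluate,
                         subsample_learning_curve)
from .simulate import ECR_NAME, simulate_dataset, read_fasta
from .timecourse import normalize_timecourse, summarize_shapes

__all__ = ["Workspace", "run_pipeline", "PipelineError"]

STAGES = ("simulate", "de", "catalog", "associate", "positional",
          "predict", "timecourse")


class PipelineError(RuntimeError):
    pass


class Workspace:
    """Lazy view of the artifacts in a pipeline output directory."""

    def __init__(self, outdir: str):
        self.outdir = str(outdir)
        os.makedirs(self.outdir, exist_ok=True)
        self._cache: dict = {}

    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    def _memo(self, key, loader):
        if key not in self._cache:
            self._cache[key] = loader()
        return self._cache[key]

    # -- inputs ----------------------------------------------------------
    @property
    def config(self) -> SimulationConfig:
        return self._memo("config",
                          lambda: SimulationConfig.from_yaml(self.path("config.yaml")))

    @property
    def samples(self) -> pd.DataFrame:
        return self._memo("samples",
                          lambda: load_sample_sheet(self.path("samples.tsv")))

    @property
    def counts(self) -> CountMatrix:
        return self._memo("counts", lambda: load_counts(
            self.path("gene_counts.tsv"), self.samples))

    @property
    def exon_counts(self) -> CountMatrix:
        return self._memo("exon_counts", lambda: load_counts(
            self.path("exon_counts.tsv"), self.samples))

    @property
    def exon_table(self) -> pd.DataFrame:
        return self._memo("exon_table", lambda: pd.read_csv(
            self.path("exons.tsv"), sep="\t", index_col=0))

    @property
    def annotation(self) -> GeneAnnotation:
        return self._memo("annotation",
                          lambda: load_annotation(self.path("annotation.gff3")))

    @property
    def promoters(self) -> Dict[str, str]:
        return self._memo("promoters",
                          lambda: read_fasta(self.path("promoters.fasta")))

    @property
    def pwms(self) -> dict:
        return self._memo("pwms", lambda: {
            p.name: p for p in read_meme(self.path("motifs.meme"))})

    @property
    def isoform_counts(self) -> pd.DataFrame:
        return self._memo("isoform_counts", lambda: pd.read_csv(
            self.path("isoform_counts.tsv"), sep="\t", index_col=0))

    @property
    def isoform_lengths(self) -> pd.Series:
        return self._memo("isoform_lengths", lambda: pd.read_csv(
            self.path("isoform_lengths.tsv"), sep="\t",
            index_col=0)["length"])

    # -- stage products --------------------------------------------------
    @property
    def size_factors(self) -> pd.Series:
        return self._memo("size_factors", lambda: pd.read_csv(
            self.path("size_factors.tsv"), sep="\t",
            index_col=0)["size_factor"])

    @property
    def de_tables(self) -> Dict[str, pd.DataFrame]:
        def load():
            long = pd.read_csv(self.path("de_results.tsv"), sep="\t")
            return {line: grp.drop(columns="cell_line").set_index("gene_id")
                            .assign(cell_line=line)
                    for line, grp in long.groupby("cell_line")}
        return self._memo("de_tables", load)

    @property
    def catalog(self) -> ResponseCatalog:
        def load():
            calls = pd.read_csv(self.path("catalog_calls.tsv"), sep="\t",
                                index_col=0)
            calls.columns.name = "cell_line"
            gene_summary = pd.read_csv(self.path("catalog_genes.tsv"),
                                       sep="\t", index_col=0)
            line_summary = pd.read_csv(self.path("catalog_lines.tsv"),
                                       sep="\t", index_col=0)
            fi = pd.read_csv(self.path("fisher_induction.tsv"), sep="\t",
                             index_col=0)
            fr = pd.read_csv(self.path("fisher_repression.tsv"), sep="\t",
                             index_col=0)
            return ResponseCatalog(calls.astype(np.int8), gene_summary,
                                   line_summary, fi, fr)
        return self._memo("catalog", load)

    @property
    def basal_expression(self) -> pd.DataFrame:
        def build():
            cm = self.counts.select(times=(0,))
            q = normalized_counts(cm, self.size_factors[cm.counts.columns])
            lines = cm.samples["cell_line"]
            return q.T.groupby(lines).mean().T
        return self._memo("basal_expression", build)

    def set(self, key, value):
        self._cache[key] = value
        return value


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(ws: Workspace, config: SimulationConfig) -> None:
    ds = simulate_dataset(config)
    ds.write(ws.outdir)
    ws.set("config", config)
    ws.set("counts", ds.counts)
    ws.set("exon_counts", ds.exon_counts)
    ws.set("annotation", ds.annotation)
    ws.set("promoters", ds.promoters)
    ws.set("pwms", {p.name: p for p in ds.pwms})
    ws.set("samples", ds.counts.samples)
    ws.set("isoform_counts", ds.isoform_counts)
    ws.set("isoform_lengths", ds.isoform_lengths)


def stage_de(ws: Workspace) -> None:
    cm = ws.counts.select(times=(0, 5))
    sf = estimate_size_factors(cm.counts)
    disp = fit_dispersions(cm, sf)
    tables = run_de_all_lines(cm, sf, disp)
    ws.set("size_factors", sf)
    ws.set("de_tables", tables)
    ws.set("dispersions", disp)
    sf.rename_axis("sample_id").to_frame().to_csv(
        ws.path("size_factors.tsv"), sep="\t")
    long = pd.concat([t.reset_index() for t in tables.values()],
                     ignore_index=True)
    long.to_csv(ws.path("de_results.tsv"), sep="\t", index=False)
    with open(ws.path("dispersion_trend.json"), "w") as fh:
        json.dump({"a0": disp.trend[0], "a1": disp.trend[1]}, fh, indent=1)
    try:
        exon_res = test_exon_de(ws.exon_counts.select(times=(0, 5)),
                                cm, sf, disp, ws.exon_table)
        exon_res.to_csv(ws.path("exon_results.tsv"), sep="\t")
        ws.set("exon_results", exon_res)
    except FileNotFoundError:
        pass  # exon counts are optional for real inputs


def stage_catalog(ws: Workspace) -> None:
    tables = ws.de_tables
    fi = fisher_combine(tables, "induction")
    fr = fisher_combine(tables, "repression")
    calls = call_responsive(tables, fi, fr)
    cat = summarize_catalog(calls, fi, fr)
    ws.set("catalog", cat)
    fi.to_csv(ws.path("fisher_induction.tsv"), sep="\t")
    fr.to_csv(ws.path("fisher_repression.tsv"), sep="\t")
    calls.to_csv(ws.path("catalog_calls.tsv"), sep="\t")
    cat.gene_summary.to_csv(ws.path("catalog_genes.tsv"), sep="\t")
    cat.line_summary.to_csv(ws.path("catalog_lines.tsv"), sep="\t")
    summary = {
        "n_lines": cat.n_lines,
        "n_responsive_genes": int((cat.calls != 0).any(axis=1).sum()),
        "n_widespread_induced": len(cat.genes_in_class("widespread", "induced")),
        "n_widespread_repressed": len(cat.genes_in_class("widespread", "repressed")),
        "n_weak_induced": int(cat.gene_summary["weak_induced"].sum()),
        "n_weak_repressed": int(cat.gene_summary["weak_repressed"].sum()),
        "n_bidirectional": int(cat.gene_summary["bidirectional"].sum()),
        "rgc": cat.line_summary["rgc"].to_dict(),
    }
    with open(ws.path("catalog_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    if cat.n_lines >= 2:
        sims, z, order = jaccard_cluster(cat)
        sims["combined"].to_csv(ws.path("jaccard_combined.tsv"), sep="\t")
        with open(ws.path("jaccard_order.json"), "w") as fh:
            json.dump({"leaf_order": order}, fh, indent=1)


def stage_associate(ws: Workspace) -> None:
    cat = ws.catalog
    basal = ws.basal_expression
    scan = rgc_correlation_scan(basal, cat.line_summary["rgc"])
    scan.to_csv(ws.path("rgc_scan.tsv"), sep="\t")
    ws.set("rgc_scan", scan)
    top_gene = scan.index[0]
    resid = residualize_and_rescan(basal, cat.line_summary["rgc"], top_gene)
    resid.to_csv(ws.path("rgc_residual_scan.tsv"), sep="\t")
    ws.set("rgc_residual_scan", resid)
    try:
        fb = isoform_fraction(ws.isoform_counts, ws.isoform_lengths)
        iso_scan = isoform_response_scan(fb, ws.de_tables)
        iso_scan.to_csv(ws.path("isoform_scan.tsv"), sep="\t")
        ws.set("isoform_scan", iso_scan)
    except FileNotFoundError:
        pass


def stage_positional(ws: Workspace) -> None:
    cat = ws.catalog
    exon_res = ws._cache.get("exon_results")
    exon_expr = None
    if exon_res is not None:
        sf = ws.size_factors
        ecm = ws.exon_counts.select(times=(0, 5))
        q = normalized_counts(ecm, sf[ecm.counts.columns])
        t0 = ecm.samples.index[ecm.samples["time_hr"] == 0]
        t5 = ecm.samples.index[ecm.samples["time_hr"] == 5]
        lengths = ws.exon_table["length"]
        exon_expr = pd.DataFrame({
            "expr_0h": q[t0].mean(axis=1) / lengths,
            "expr_5h": q[t5].mean(axis=1) / lengths,
        })
    tss_map = select_tss_map(ws.annotation, cat, exon_res, exon_expr,
                             ws.exon_table if exon_res is not None else None)
    tss_map.rename_axis("gene_id").to_csv(ws.path("selected_tss.tsv"),
                                          sep="\t")
    records = build_neighbor_records(ws.annotation, cat, ws.de_tables,
                                     tss_map)
    enrichment: dict = {}
    if not records.empty:
        profiles = build_profiles(records)
        profiles.to_csv(ws.path("positional_profiles.tsv"), sep="\t",
                        index=False)
        enrichment["background_fraction_10_20kb"] = profiles.attrs["background"]
        ws.set("positional_profiles", profiles)

    chrom_of = {g.gene_id: g.chrom for g in ws.annotation}
    weak = list(cat.gene_summary.index[cat.gene_summary["weak_induced"]])
    induced = list(cat.calls.index[(cat.calls == 1).any(axis=1)])
    if weak and induced:
        enrichment["weak_proximity"] = proximity_enrichment(
            weak, induced, tss_map, chrom_of)

    if ECR_NAME in ws.pwms:
        widespread_ind = cat.genes_in_class("widespread", "induced")
        nonresponsive = [g for g in cat.calls.index
                         if (cat.calls.loc[g] == 0).all()]
        if len(nonresponsive) >= 100 and widespread_ind:
            thr = calibrate_motif_threshold(
                ws.pwms[ECR_NAME],
                [ws.promoters[g] for g in nonresponsive
                 if g in ws.promoters])
            enrichment["ecre_promoter"] = motif_enrichment(
                ws.promoters, widespread_ind, list(cat.calls.index),
                ws.pwms[ECR_NAME], thr.cutoff)
    with open(ws.path("positional_enrichment.json"), "w") as fh:
        json.dump(enrichment, fh, indent=1, default=float)
    ws.set("positional_enrichment", enrichment)


def _prediction_inputs(ws: Workspace):
    basal = ws.basal_expression
    pwms = ws.pwms
    tf_names = [t for t in pwms if t in basal.index]
    tf_expression = basal.loc[tf_names]
    cat = ws.catalog
    nonresponsive = [g for g in cat.calls.index
                     if (cat.calls.loc[g] == 0).all()
                     and not cat.gene_summary.loc[g, ["weak_induced",
                                                      "weak_repressed"]].any()]
    nr_prom = [ws.promoters[g] for g in nonresponsive if g in ws.promoters]
    thresholds = {}
    for tf in tf_names:
        try:
            thresholds[tf] = calibrate_motif_threshold(pwms[tf], nr_prom)
        except Exception:
            continue
    return basal, tf_expression, thresholds


def stage_predict(ws: Workspace, seed: int = 0,
                  learning_curve: bool = False,
                  n_trees: int = 500) -> None:
    cat = ws.catalog
    basal, tf_expression, thresholds = _prediction_inputs(ws)
    results = {}
    for direction in ("induction", "repression"):
        sets = build_matched_sets(cat, ws.de_tables, direction)
        if not sets:
            continue
        fm = build_features(sets, tf_expression, thresholds, ws.promoters,
                            ws.pwms, basal)
        fm.to_csv(ws.path(f"features_{direction}.tsv"), sep="\t", index=False)
        res = loco_evaluate(fm, n_trees=n_trees,
                            seed=derive_seed(seed, f"loco:{direction}"))
        res["importances"].rename_axis("feature").to_csv(
            ws.path(f"importances_{direction}.tsv"), sep="\t")
        pd.Series(res["per_line"], name="accuracy").rename_axis(
            "cell_line").to_csv(
            ws.path(f"loco_accuracy_{direction}.tsv"), sep="\t")
        results[direction] = {"accuracy": res["accuracy"],
                              "n_rows": len(fm),
                              "n_genes": len(sets)}
        if learning_curve:
            n_lines = cat.n_lines
            n_values = [n for n in (5, 8, 12, 16, min(20, n_lines - 1))
                        if 4 <= n <= n_lines - 1]

            def builder(msets):
                return build_features(msets, tf_expression, thresholds,
                                      ws.promoters, ws.pwms, basal)

            lc = subsample_learning_curve(
                cat, ws.de_tables, direction, builder,
                n_values=sorted(set(n_values)), reps=10, n_trees=100,
                seed=derive_seed(seed, f"curve:{direction}"))
            lc["curve"].to_csv(ws.path(f"learning_curve_{direction}.tsv"),
                               sep="\t", index=False)
            results[direction]["asymptote"] = lc["asymptote"]
            results[direction]["asymptote_ci"] = list(lc["asymptote_ci"])
    with open(ws.path("prediction_summary.json"), "w") as fh:
        json.dump(results, fh, indent=1, default=float)
    ws.set("prediction_summary", results)


def stage_timecourse(ws: Workspace) -> Optional[pd.DataFrame]:
    have = ws.counts.samples.groupby("cell_line")["time_hr"].agg(set)
    tc_lines = [l for l, ts in have.items() if {0, 1, 3, 5, 7} <= ts]
    if not tc_lines:
        return None
    profiles = normalize_timecourse(ws.counts, tc_lines)
    cat = ws.catalog
    sets = {
        "widespread_induced": cat.genes_in_class("widespread", "induced"),
        "widespread_repressed": cat.genes_in_class("widespread", "repressed"),
        "restricted_induced": cat.genes_in_class("restricted", "induced"),
    }
    summary = summarize_shapes(profiles, sets)
    summary["profiles"].to_csv(ws.path("timecourse_shapes.tsv"), sep="\t",
                               index=False)
    summary["median_trajectories"].to_csv(
        ws.path("timecourse_medians.tsv"), sep="\t", index=False)
    ws.set("timecourse_profiles", summary["profiles"])
    return summary["profiles"]


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config: SimulationConfig, outdir: str,
                 stages: Optional[List[str]] = None,
                 learning_curve: bool = False) -> Workspace:
    """Run the requested stages in order, logging progress and parameters."""
    ws = Workspace(outdir)
    stages = list(STAGES) if stages is None else list(stages)
    log: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
    }
    for stage in stages:
        t0 = time.time()
        note = ""
        try:
            if stage == "simulate":
                stage_simulate(ws, config)
            elif stage == "de":
                stage_de(ws)
            elif stage == "catalog":
                stage_catalog(ws)
            elif stage == "associate":
                stage_associate(ws)
            elif stage == "positional":
                stage_positional(ws)
            elif stage == "predict":
                stage_predict(ws, seed=config.seed,
                              learning_curve=learning_curve)
            elif stage == "timecourse":
                if stage_timecourse(ws) is None:
                    note = "skipped: no line has the 5-point time course"
            else:
                raise PipelineError(f"unknown stage {stage!r}")
        except Exception as exc:
            log["stages"].append({"stage": stage, "status": "failed",
                                  "error": str(exc)})
            with open(ws.path("pipeline_log.json"), "w") as fh:
                json.dump(log, fh, indent=1, default=str)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        log["stages"].append({"stage": stage, "status": "ok",
                              "seconds": round(time.time() - t0, 2),
                              "note": note})
    with open(ws.path("pipeline_log.json"), "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    return ws
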