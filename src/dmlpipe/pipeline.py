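"""End-to-end pipeline orchestration with logging and a run report.

Stages run in the fixed order simulate → tracks → snps → methylation →
dml → annotate → enrich. Each stage logs input/output record counts; the
JSON report carries the full configuration, the accounting chain
(candidates → SNP-removed → retained, hyper/hypo shares), methylation
class summaries, feature tables and enriched terms.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, dml, intervals, methylation, simulate, snps

logger = logging.getLogger("dmlpipe")

STAGES = ("simulate", "tracks", "snps", "methylation", "dml", "annotate",
          "enrich")


def setup_logging(log_file=None, level=logging.INFO) -> None:
    handlers = [logging.StreamHandler()]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=level, handlers=handlers, force=True,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage toggles for one pipeline run.

    Defaults are the published analysis settings: 5x coverage floor,
    99.9th-percentile coverage ceiling, 50-point difference and q < 0.01
    DML thresholds, enrichment p < 0.01, 1 kb flanks, SNP screen with
    minimum informative coverage 5 and 0.1/0.85 het/hom fractions.
    """

    outdir: str = "dmlpipe_out"
    genome_fasta: str | None = None
    annotation_gff3: str | None = None
    coverage_dir: str | None = None
    pileup_dir: str | None = None
    gene2go_tsv: str | None = None

    lo_count: int = 5
    high_perc: float = 99.9
    diff_threshold: float = 50.0
    q_threshold: float = 0.01
    enrich_p: float = 0.01
    flank_width: int = 1000
    snp_min_cov: int = 5
    snp_het_min: float = 0.1
    snp_hom_min: float = 0.85

    seed: int = 0
    stages: tuple = STAGES
    sim: simulate.SimConfig | None = None

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold <= 1 or not 0 < self.enrich_p <= 1:
            raise ValueError("q/enrichment thresholds must be in (0, 1]")
        if not 0 < self.diff_threshold <= 100:
            raise ValueError("diff_threshold must be in (0, 100]")
        if self.lo_count < 1 or self.flank_width <= 0:
            raise ValueError("lo_count and flank_width must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run report dict.

    Stage dependencies are strict: a disabled upstream stage with a
    downstream stage enabled fails fast unless the corresponding input
    files are provided.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}}
    enabled = set(config.stages)

    # --- simulate -----------------------------------------------------
    if "simulate" in enabled:
        sim_cfg = config.sim or simulate.SimConfig(seed=config.seed)
        data = simulate.simulate_dataset(sim_cfg)
        sequences, sizes = data["sequences"], data["chrom_sizes"]
        annotation = data["annotation"]
        counts, truth = data["counts"], data["truth"]
        pileups = data["pileups"]
        gene2go = {r.gene_id: set(r.go_ids.split(","))
                   for r in data["gene2go"].itertuples(index=False)}
        samples = data["samples"]
        simulate.write_fasta(sequences, outdir / "genome.fa")
        intervals.write_gff3(
            {k: annotation[k] for k in ("gene", "exon", "CDS", "lncRNA")},
            outdir / "annotation.gff3")
        truth.write(outdir / "truth.tsv")
        simulate.write_gene2go(data["gene2go"], outdir / "gene2go.tsv")
        samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        for sid, table in counts.items():
            simulate.write_coverage(table, outdir / f"{sid}.cov.tsv")
        for sid, table in pileups.items():
            simulate.write_pileups(table, outdir / f"{sid}.pileup.tsv")
        report["stages"]["simulate"] = {
            "n_chroms": len(sizes), "n_cpgs": len(truth.loci),
            "n_planted_dml": int(len(truth.dml_truth)),
            "n_planted_snps": int(len(truth.snp_truth)),
        }
        logger.info("simulate: %d CpGs, %d planted DML, %d planted SNPs",
                    len(truth.loci), len(truth.dml_truth),
                    len(truth.snp_truth))
    else:
        missing = [n for n in ("genome_fasta", "annotation_gff3",
                               "coverage_dir")
                   if getattr(config, n) is None]
        if missing and enabled - {"simulate"}:
            raise ValueError(
                f"stage 'simulate' disabled but inputs missing: {missing}")
        sequences, sizes = simulate.read_fasta(config.genome_fasta)
        annotation = intervals.read_gff3(config.annotation_gff3)
        cov_dir = Path(config.coverage_dir)
        counts = {}
        sample_rows = []
        meta = pd.read_csv(cov_dir / "samples.tsv", sep="\t")
        cg = intervals.find_cg_motifs(sequences)
        for row in meta.itertuples(index=False):
            raw = methylation.read_bismark_coverage(
                cov_dir / f"{row.sample_id}.cov.tsv")
            counts[row.sample_id] = methylation.assign_strand(raw, cg)
            sample_rows.append(row)
        samples = pd.DataFrame(sample_rows)
        truth = None
        pileups = None
        if config.pileup_dir is not None:
            pileups = {
                sid: simulate.read_pileups(
                    Path(config.pileup_dir) / f"{sid}.pileup.tsv")
                for sid in samples["sample_id"]}
        gene2go = (annotate.read_gene2go(config.gene2go_tsv)
                   if config.gene2go_tsv else None)

    # --- tracks -------------------------------------------------------
    tracks = None
    cg_track = intervals.find_cg_motifs(sequences)
    if "tracks" in enabled:
        extra = {k: annotation[k] for k in ("TE", "lncRNA")
                 if k in annotation and len(annotation[k])}
        tracks = intervals.build_feature_tracks(
            annotation["gene"], annotation["exon"], annotation["CDS"],
            sizes, flank_width=config.flank_width, extra=extra)
        for cls, track in tracks.items():
            intervals.write_bed(track, outdir / f"track_{cls}.bed")
        report["stages"]["tracks"] = {
            "total_cpgs": len(cg_track),
            "cpgs_per_class": {
                cls: intervals.count_cpgs_in_track(cg_track, t)
                for cls, t in tracks.items()},
        }
        logger.info("tracks: %d CG motifs across %d classes",
                    len(cg_track), len(tracks))

    # --- snps ---------------------------------------------------------
    snp_set = snps.SnpSet(pd.DataFrame(columns=["chrom", "pos", "genotype"]))
    if "snps" in enabled:
        if pileups is None:
            raise ValueError("stage 'snps' enabled but no pileups available")
        merged = snps.screen_genome(
            pileups, "merged", config.snp_min_cov, config.snp_het_min,
            config.snp_hom_min)
        per_sample = snps.screen_genome(
            pileups, "per_sample", config.snp_min_cov, config.snp_het_min,
            config.snp_hom_min)
        snp_set = snps.union_snp_sets(merged, per_sample)
        snps.write_snp_bed(snp_set, outdir / "ct_snps.bed")
        snps.write_snp_vcf(snp_set, outdir / "ct_snps.vcf")
        report["stages"]["snps"] = {
            "merged_calls": len(merged), "per_sample_calls": len(per_sample),
            "union_exclusion_set": len(snp_set),
        }
        logger.info("snps: %d merged, %d per-sample, %d in union",
                    len(merged), len(per_sample), len(snp_set))

    # --- methylation --------------------------------------------------
    # Global characterization uses the SNP-excluded matrix; the DML test
    # runs on the full united background and removes SNP overlaps at the
    # candidate stage, which is where the published accounting lives.
    united = None
    matrix = None
    if "methylation" in enabled:
        destranded = {sid: methylation.destrand(tbl)
                      for sid, tbl in counts.items()}
        raw = methylation.build_matrix(destranded, samples)
        filtered = methylation.filter_coverage(raw, config.lo_count,
                                               config.high_perc)
        normalized = methylation.normalize_coverage(filtered)
        united = methylation.unite(normalized, config.lo_count)
        matrix, n_removed = methylation.apply_snp_exclusion(united, snp_set)
        per_locus, class_summary = methylation.classify_loci(matrix)
        corr = methylation.sample_correlations(matrix)
        _, evr = methylation.sample_pca(matrix)
        methylation.write_matrix_tsv(matrix, outdir / "united_matrix.tsv")
        methylation.write_bedgraph(matrix, outdir / "cpg_5x.bedgraph")
        report["stages"]["methylation"] = {
            "destranded_loci": len(raw.loci),
            "united_loci": len(united.loci),
            "snp_excluded": n_removed,
            "analyzed_loci": len(matrix.loci),
            "class_summary": class_summary.to_dict(orient="records"),
            "min_pairwise_correlation": float(np.nanmin(corr.to_numpy())),
            "pc1_variance_fraction": float(evr[0]) if len(evr) else None,
        }
        logger.info("methylation: %d destranded -> %d united -> %d after "
                    "SNP exclusion", len(raw.loci), len(united.loci),
                    len(matrix.loci))

    # --- dml ----------------------------------------------------------
    records = None
    accounting = None
    if "dml" in enabled:
        if united is None:
            raise ValueError("stage 'dml' requires stage 'methylation'")
        fits = dml.fit_matrix(united, covariate="stage")
        records, accounting = dml.call_dml(
            fits, snp_set, config.q_threshold, config.diff_threshold)
        accounting.update(dml.direction_shares(accounting["hypo"],
                                               accounting["hyper"]))
        dml.write_dml_bed(records, outdir / "dml.bed")
        dml.write_dml_tsv(records, outdir / "dml.tsv")
        report["stages"]["dml"] = accounting
        logger.info("dml: %d candidates, %d SNP-removed, %d retained "
                    "(%d hyper / %d hypo)", accounting["candidates"],
                    accounting["snp_removed"], accounting["retained"],
                    accounting["hyper"], accounting["hypo"])

    # --- annotate -----------------------------------------------------
    if "annotate" in enabled:
        if records is None or tracks is None:
            raise ValueError("stage 'annotate' requires 'dml' and 'tracks'")
        dml_loci = records[records["is_dml"]][["chrom", "pos"]]
        overlap = annotate.overlap_features(dml_loci, tracks)
        bg_counts = annotate.partition_counts(matrix.loci, tracks)
        dml_counts = annotate.partition_counts(dml_loci, tracks)
        cont = (annotate.contingency_test(bg_counts, dml_counts)
                if len(dml_loci) else None)
        density = annotate.chromosome_density(dml_loci, matrix.loci,
                                              tracks["gene"])
        per_gene = annotate.dml_per_gene(dml_loci, tracks["gene"])
        overlap.to_csv(outdir / "dml_feature_overlap.tsv", sep="\t",
                       index=False)
        density.to_csv(outdir / "dml_per_chromosome.tsv", sep="\t",
                       index=False)
        per_gene.rename("n_dml").to_csv(outdir / "dml_per_gene.tsv",
                                        sep="\t")
        report["stages"]["annotate"] = {
            "feature_overlap": overlap.to_dict(orient="records"),
            "contingency": None if cont is None else {
                "statistic": cont["statistic"], "df": cont["df"],
                "p_value": cont["p_value"]},
            "genes_with_dml": int(len(per_gene)),
            "max_dml_in_one_gene": int(per_gene.max()) if len(per_gene)
            else 0,
        }
        logger.info("annotate: %d genes contain DML", len(per_gene))

    # --- enrich -------------------------------------------------------
    if "enrich" in enabled:
        if records is None or tracks is None or gene2go is None:
            raise ValueError(
                "stage 'enrich' requires 'dml', 'tracks' and a gene2go map")
        universe_track = tracks["gene"]
        universe = set(
            annotate.dml_per_gene(matrix.loci, universe_track).index)
        interest = annotate.genes_with_dml(records, universe_track) & universe
        if interest:
            enr = annotate.go_enrichment(interest, universe, gene2go,
                                         config.enrich_p)
            annotate.write_enrichment_tsv(enr, outdir / "go_enrichment.tsv")
            sig = enr[enr["significant"]]
            report["stages"]["enrich"] = {
                "universe_genes": len(set(universe) & set(gene2go)),
                "interest_genes": len(interest),
                "terms_tested": len(enr),
                "terms_significant": int(len(sig)),
                "significant_terms": sig["go_id"].tolist(),
            }
        else:
            report["stages"]["enrich"] = {
                "universe_genes": len(universe), "interest_genes": 0,
                "terms_tested": 0, "terms_significant": 0,
                "significant_terms": []}
        logger.info("enrich: %d significant terms",
                    report["stages"]["enrich"]["terms_significant"])

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    _write_text_report(report, outdir / "report.txt")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def _write_text_report(report: dict, path) -> None:
    lines = ["dmlpipe run report", "=" * 60]
    for stage, info in report["stages"].items():
        lines.append(f"\n[{stage}]")
        for k, v in info.items():
            lines.append(f"  {k}: {v}")
    Path(path).write_text("\n".join(lines) + "\n")
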