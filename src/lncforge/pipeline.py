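"""End-to-end orchestration: consensus -> identification -> characterization.

The pipeline is driven by a single configuration (YAML on disk or a
PipelineConfig in memory) whose defaults equal the published thresholds of the
silkworm study this package operationalizes.  Every threshold actually applied
is logged, and outputs are plain TSV/GTF/JSON so runs are auditable and
byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation_io as aio
from . import assembly_consensus as consensus
from . import coding_potential as codpot
from . import coexpression_network as network
from . import expression_specificity as xspec
from . import lncrna_identification as ident
from . import rna_interactions as interact
from .synthetic_data import default_coding_corpora

logger = logging.getLogger("lncforge")

__all__ = [
    "PipelineConfig",
    "train_default_scorer",
    "run_consensus",
    "run_identify",
    "run_characterize",
]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; defaults are the study's values."""

    # inputs
    candidates_gtf: str = ""
    reference_gtf: str = ""
    genome_fasta: str = ""
    scaffolds_tsv: str = ""
    fpkm_tsv: str = ""
    counts_tsv: str = ""
    samples_tsv: str = ""
    hits_tsv: str = ""
    mirna_gff3: str = ""
    mirna_fasta: str = ""
    conserved_tsv: str = ""
    external_scores_tsv: str = ""
    term_mapping_tsv: str = ""
    subnetworks_tsv: str = ""
    repeats_bed: str = ""
    outdir: str = "lncforge_out"
    # thresholds
    filters: ident.FilterConfig = field(default_factory=ident.FilterConfig)
    js_cutoff: float = 0.25
    sex_lfc_threshold: float = 1.0
    sex_q_threshold: float = 0.05
    locus_ratio_threshold: float = 0.75
    soft_power: float = 9.0
    cut_height: float = 0.995
    min_module_size: int = 30
    merge_cor: float = 0.70
    edge_threshold: float = 0.15
    hub_top_k: int = 5
    min_expressed_samples: int = 2
    min_distinct_mirnas: int = 1
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filters = ident.FilterConfig(**raw.pop("filters", {}))
        return cls(filters=filters, **raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def train_default_scorer(seed: int, n_per_class: int = 500,
                         threshold: float = 0.345,
                         recalibrate: bool = False) -> codpot.TranscriptScorer:
    """Train the coding-potential scorer on the default synthetic corpora."""
    coding, orfs, noncoding = default_coding_corpora(n_per_class, seed)
    table = codpot.build_hexamer_table(orfs, noncoding)
    feats = np.array([codpot.sequence_features(s, table) for s in coding + noncoding])
    labels = np.array([1] * len(coding) + [0] * len(noncoding))
    model = codpot.fit_coding_model(feats, labels, seed=seed, threshold=threshold,
                                    recalibrate=recalibrate, table=table)
    logger.info("coding scorer trained: held-out AUC %.4f, threshold %.3f",
                model.holdout_auc, model.threshold)
    return codpot.TranscriptScorer(model, table)


def run_consensus(manifest_tsv, out_gtf, report_tsv=None) -> list:
    """Stringent selection + merge from a manifest (assembler, tissue, gtf_path)."""
    manifest = pd.read_csv(manifest_tsv, sep="\t")
    base = Path(manifest_tsv).parent
    assemblies = []
    for _, row in manifest.iterrows():
        gtf = Path(row["gtf_path"])
        if not gtf.is_absolute():
            gtf = base / gtf
        models = aio.read_gtf(gtf, strand_policy="drop")
        assemblies.append((row["assembler"], row["tissue"], models))
    table = consensus.build_support(assemblies)
    kept = consensus.stringent_select(table)
    merged = consensus.merge_transcripts(kept)
    aio.write_gtf(merged, out_gtf)
    if report_tsv is not None:
        pd.DataFrame([
            {"metric": "input_chains", "value": len(table.chains)},
            {"metric": "single_exon_skipped", "value": table.n_single_exon_skipped},
            {"metric": "stringent_chains", "value": len(kept)},
            {"metric": "merged_transcripts", "value": len(merged)},
            {"metric": "loci", "value": len({t.locus_id for t in merged})},
        ]).to_csv(report_tsv, sep="\t", index=False)
    logger.info("consensus: %d chains -> %d stringent -> %d merged",
                len(table.chains), len(kept), len(merged))
    return merged


def run_identify(cfg: PipelineConfig, scorer=None):
    """Cascade + categories + feature table; writes lncrna.gtf, filter_report.tsv
    and features.tsv under cfg.outdir and returns (records, report)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_path = Path(cfg.genome_fasta)
    if not genome_path.exists():
        raise FileNotFoundError(f"genome not found: {genome_path}")
    genome = aio.read_fasta(genome_path)
    candidates = aio.read_gtf(cfg.candidates_gtf)
    reference = aio.read_gtf(cfg.reference_gtf)
    scaffolds = aio.read_scaffold_lengths(cfg.scaffolds_tsv) if cfg.scaffolds_tsv else None
    expression = (pd.read_csv(cfg.fpkm_tsv, sep="\t", index_col=0)
                  if cfg.fpkm_tsv else None)
    hits = pd.read_csv(cfg.hits_tsv, sep="\t") if cfg.hits_tsv else None
    external = (pd.read_csv(cfg.external_scores_tsv, sep="\t", index_col=0)
                if cfg.external_scores_tsv else None)
    if scorer is None:
        scorer = train_default_scorer(cfg.seed)
    for name, value in asdict(cfg.filters).items():
        logger.info("filter threshold %s = %s", name, value)
    records, report = ident.apply_filter_cascade(
        candidates, reference, genome, cfg.filters, scorer=scorer,
        homology_hits=hits, scaffolds=scaffolds, expression=expression,
        external_scores=external,
    )
    aio.write_gtf([r.transcript for r in records], outdir / "lncrna.gtf")
    report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    repeats = aio.read_intervals(cfg.repeats_bed, "bed") if cfg.repeats_bed else None
    features = ident.transcript_features(records, genome, repeats)
    features.to_csv(outdir / "features.tsv", sep="\t")
    counts = {c: sum(1 for r in records if r.category == c)
              for c in ("lincRNA", "ilncRNA", "lncNAT")}
    logger.info("identified %d lncRNAs (%s)", len(records), counts)
    return records, report


def run_characterize(cfg: PipelineConfig, records=None):
    """Specificity, sex bias, interactions and network reports + summary JSON."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if records is None:
        lnc_models = aio.read_gtf(outdir / "lncrna.gtf")
    else:
        lnc_models = [r.transcript for r in records]
    lnc_ids = [t.transcript_id for t in lnc_models]
    genome = aio.read_fasta(cfg.genome_fasta)
    fpkm = xspec.ExpressionMatrix.read(cfg.fpkm_tsv, cfg.samples_tsv, kind="fpkm")
    counts = xspec.ExpressionMatrix.read(cfg.counts_tsv, cfg.samples_tsv, kind="counts")
    summary: dict = {"n_lncrna": len(lnc_models),
                     "n_loci": len({t.locus_id for t in lnc_models})}
    for cat in ("lincRNA", "ilncRNA", "lncNAT"):
        summary[f"n_{cat}"] = sum(
            1 for t in lnc_models if t.attributes.get("category") == cat)

    # --- tissue specificity -------------------------------------------------
    lnc_fpkm = fpkm.values.loc[[i for i in lnc_ids if i in fpkm.values.index]]
    spec = xspec.js_specificity(
        xspec.ExpressionMatrix(lnc_fpkm, fpkm.samples, kind="fpkm"))
    spec["tissue_specific"] = xspec.classify_tissue_specific(spec, cfg.js_cutoff)
    spec.to_csv(outdir / "specificity.tsv", sep="\t")
    valid = spec["valid"].astype(bool)
    summary["n_tissue_specific"] = int(spec.loc[valid, "tissue_specific"].sum())

    # --- sex bias -----------------------------------------------------------
    lnc_counts = counts.values.loc[[i for i in lnc_ids if i in counts.values.index]]
    sexbias = xspec.sex_bias_table(
        xspec.ExpressionMatrix(lnc_counts, counts.samples, kind="counts"),
        lfc_threshold=cfg.sex_lfc_threshold, q_threshold=cfg.sex_q_threshold)
    sexbias.to_csv(outdir / "sexbias.tsv", sep="\t", index=False)
    biased_any = (sexbias[sexbias["call"] != "unbiased"]
                  .groupby("transcript_id").size())
    locus_of = {t.transcript_id: t.locus_id for t in lnc_models}
    calls: dict[str, list[bool]] = {}
    for tid in lnc_ids:
        calls.setdefault(locus_of[tid], []).append(tid in biased_any.index)
    locus_results = xspec.locus_sex_bias_ratio(calls, cfg.locus_ratio_threshold)
    pd.DataFrame([{"locus_id": r.locus_id, "ratio": r.ratio, "biased": r.biased,
                   "n_isoforms": r.n_isoforms, "n_biased": r.n_biased}
                  for r in locus_results]).to_csv(
        outdir / "locus_sexbias.tsv", sep="\t", index=False)
    summary["n_sex_biased_loci"] = sum(r.biased for r in locus_results)
    summary["sex_biased_locus_fraction"] = (
        summary["n_sex_biased_loci"] / len(locus_results) if locus_results else 0.0)

    # --- miRNA precursors and ceRNA candidates ------------------------------
    if cfg.mirna_gff3:
        mirna_loci = aio.read_intervals(cfg.mirna_gff3, "gff3")
        precursors = interact.precursor_overlap(lnc_models, mirna_loci)
        precursors.to_csv(outdir / "precursors.tsv", sep="\t", index=False)
        summary["n_precursor_loci"] = int(precursors["locus_id"].nunique())
    if cfg.mirna_fasta and cfg.conserved_tsv:
        mirnas = {rec.id: str(rec.seq) for rec in _iter_fasta(cfg.mirna_fasta)}
        conserved: dict[str, list[tuple[int, int]]] = {}
        cons_df = pd.read_csv(cfg.conserved_tsv, sep="\t")
        for _, row in cons_df.iterrows():
            conserved.setdefault(row["transcript_id"], []).append(
                (int(row["start"]), int(row["end"])))
        hits: list = []
        lengths = {}
        for t in lnc_models:
            if t.transcript_id not in conserved:
                continue
            seq = aio.spliced_sequence(t, genome)
            lengths[t.transcript_id] = len(seq)
            for mid, mseq in mirnas.items():
                hits.extend(interact.scan_mre_sites(seq, mseq, t.transcript_id, mid))
        pd.DataFrame([h.__dict__ for h in hits]).to_csv(
            outdir / "mre_hits.tsv", sep="\t", index=False)
        cerna = interact.cerna_filter(hits, conserved, cfg.min_distinct_mirnas, lengths)
        cerna.to_csv(outdir / "cerna.tsv", sep="\t", index=False)
        summary["n_cerna_candidates"] = len(cerna)

    # --- co-expression network ----------------------------------------------
    expr = np.log2(fpkm.values + 1.0)
    expressed = (fpkm.values > 0).sum(axis=1) >= cfg.min_expressed_samples
    expr = expr.loc[expressed]
    adjacency = network.adjacency_from_expression(expr, beta=cfg.soft_power)
    tom = network.tom_matrix(adjacency)
    assignment = network.detect_modules(tom, adjacency.ids,
                                        cfg.min_module_size, cfg.cut_height)
    if (assignment != network.UNASSIGNED).any():
        assignment, eigengenes = network.module_eigengene_and_merge(
            expr.loc[assignment.index], assignment, cfg.merge_cor)
        meta = fpkm.samples.loc[eigengenes.index]
        traits = pd.get_dummies(meta["tissue"]).astype(int)
        traits["female"] = (meta["sex"] == "F").astype(int)
        kme, module_trait = network.kme_and_trait_correlation(
            expr.loc[assignment.index], eigengenes, traits)
        modules_df = pd.DataFrame({"module": assignment})
        for m in kme.columns:
            modules_df[f"kME_{m}"] = kme[m]
        modules_df.to_csv(outdir / "modules.tsv", sep="\t")
        module_trait.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
        summary["n_modules"] = int((assignment != network.UNASSIGNED).sum() > 0
                                   and assignment[assignment != network.UNASSIGNED].nunique())
        summary["max_module_trait_r"] = float(module_trait["r"].abs().max())
        if cfg.term_mapping_tsv:
            terms_df = pd.read_csv(cfg.term_mapping_tsv, sep="\t")
            term_map = {t: list(g["gene_id"]) for t, g in terms_df.groupby("term_id")}
            enr_frames = []
            for m in assignment[assignment != network.UNASSIGNED].unique():
                members = assignment.index[assignment == m]
                enr = network.hypergeometric_enrichment(members, term_map,
                                                        assignment.index)
                enr["module"] = m
                enr_frames.append(enr)
            pd.concat(enr_frames, ignore_index=True).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False)
        if cfg.subnetworks_tsv:
            sub_df = pd.read_csv(cfg.subnetworks_tsv, sep="\t")
            subnets = {lbl: list(g["gene_id"]) for lbl, g in sub_df.groupby("label")}
            tom_df = pd.DataFrame(tom, index=adjacency.ids, columns=adjacency.ids)
            hubs = network.hub_selection(tom_df, cfg.edge_threshold,
                                         [i for i in lnc_ids if i in tom_df.index],
                                         subnets, cfg.hub_top_k)
            pd.DataFrame([h.__dict__ for h in hubs]).to_csv(
                outdir / "hubs.tsv", sep="\t", index=False)
            summary["n_hub_lncrnas"] = len({h.lncrna_id for h in hubs})

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _iter_fasta(path):
    from Bio import SeqIO

    return SeqIO.parse(str(path), "fasta")
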