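"""Fully specified toy transcriptome with a machine-readable truth manifest.

The generator emulates the data structure of a multi-tissue lncRNA survey:
a multi-scaffold genome, a coding reference annotation, a candidate transcript
set with planted lncRNA classes (intergenic, intronic, antisense) and
per-stage decoys for the identification cascade, pseudo-assembler replicate
GTFs, tissue- and sex-structured negative-binomial expression with correlated
modules, planted miRNA precursors and seed sites, and tables of homology hits
and conserved regions.  Everything is deterministic in the seed.

Coding sequences are drawn from a skewed codon-usage model (one preferred
codon per amino acid), which creates a learnable in-frame hexamer signal;
noncoding background is a slightly AT-rich i.i.d. model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .annotation_io import (
    IntervalSet,
    SequenceStore,
    TranscriptModel,
    reverse_complement,
    write_fasta,
    write_gtf,
)
from .expression_specificity import ExpressionMatrix
from .orf import find_max_orf

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "generate_dataset",
    "write_dataset",
    "simulate_expression",
    "simulate_assembly_replicates",
    "plant_interactions",
    "write_truth",
    "read_truth",
    "random_noncoding",
    "random_coding_orf",
    "default_coding_corpora",
    "simulate_block_expression",
    "simulate_sex_counts",
]

DEFAULT_TISSUES = ("brain", "testis", "ovary", "fatbody", "midgut",
                   "silkgland", "malpighian", "integument")

# ---------------------------------------------------------------------------
# Sequence models
# ---------------------------------------------------------------------------

_NONCODING_BASES = np.array(list("ACGT"))
_NONCODING_PROBS = np.array([0.30, 0.20, 0.20, 0.30])  # slightly AT-rich


def _codon_model() -> tuple[list[str], np.ndarray]:
    """Sense codons with a skewed usage: the alphabetically first codon of
    each amino acid gets weight 0.7, the rest share 0.3."""
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(standard_dna_table.forward_table.items()):
        if codon in ("ATG",):  # Met handled by the start codon itself
            pass
        by_aa.setdefault(aa, []).append(codon)
    codons, weights = [], []
    for aa in sorted(by_aa):
        cods = by_aa[aa]
        for i, c in enumerate(cods):
            codons.append(c)
            if len(cods) == 1:
                weights.append(1.0)
            else:
                weights.append(0.7 if i == 0 else 0.3 / (len(cods) - 1))
    w = np.array(weights)
    return codons, w / w.sum()


_CODONS, _CODON_PROBS = _codon_model()


def random_noncoding(rng: np.random.Generator, length: int,
                     max_orf_aa: int | None = 100, max_attempts: int = 1000) -> str:
    """i.i.d. background sequence, rejection-sampled to bound the longest ORF."""
    for _ in range(max_attempts):
        seq = "".join(rng.choice(_NONCODING_BASES, size=length, p=_NONCODING_PROBS))
        if max_orf_aa is None or find_max_orf(seq)[0] <= max_orf_aa:
            return seq
    raise RuntimeError(f"could not draw a {length} nt sequence with ORF <= {max_orf_aa} aa")


def random_coding_orf(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + (n_aa - 1) codons from the skewed usage model + TAA."""
    body = rng.choice(len(_CODONS), size=n_aa - 1, p=_CODON_PROBS)
    return "ATG" + "".join(_CODONS[i] for i in body) + "TAA"


def default_coding_corpora(n_per_class: int, seed: int,
                           min_aa: int = 150, max_aa: int = 350
                           ) -> tuple[list[str], list[str], list[str]]:
    """(coding transcripts, their ORFs, noncoding transcripts) for training
    the coding-potential model.  Coding transcripts carry short UTRs around a
    codon-model ORF; noncoding transcripts are background >= 210 nt."""
    rng = np.random.default_rng(seed)
    coding, orfs, noncoding = [], [], []
    for _ in range(n_per_class):
        aa = int(rng.integers(min_aa, max_aa + 1))
        orf = random_coding_orf(rng, aa)
        utr5 = random_noncoding(rng, int(rng.integers(20, 80)), max_orf_aa=None)
        utr3 = random_noncoding(rng, int(rng.integers(30, 120)), max_orf_aa=None)
        coding.append(utr5 + orf + utr3)
        orfs.append(orf)
    for _ in range(n_per_class):
        length = int(rng.integers(210, 2000))
        noncoding.append(random_noncoding(rng, length, max_orf_aa=100))
    return coding, orfs, noncoding


# ---------------------------------------------------------------------------
# Configuration and dataset containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    seed: int
    n_scaffolds: int = 10
    scaffold_length: int = 200_000
    n_mrna: int = 300
    n_lincrna: int = 50
    n_ilncrna: int = 20
    n_lncnat: int = 30
    n_decoys_per_stage: int = 10  # stages 1-6
    tissues: tuple = DEFAULT_TISSUES
    module_spec: tuple = ()  # (tissue, n_members, strength); default filled below
    specific_fraction: float = 0.5
    sex_biased_fraction: float = 0.2
    sex_fold_change: float = 4.0
    nb_dispersion: float = 0.1
    library_size: int = 1_000_000
    n_mirnas: int = 12
    n_precursors: int = 5
    n_antisense_mirnas: int = 2
    n_mre_lncrnas: int = 10
    assemblers: tuple = ("cufflinks", "scripture", "stringtie")
    inclusion_prob_expressed: float = 0.95
    inclusion_prob_silent: float = 0.05
    singleton_fraction: float = 0.05
    end_margin: int = 2000

    def __post_init__(self) -> None:
        for name in ("n_scaffolds", "scaffold_length", "n_mrna", "n_lincrna",
                     "n_ilncrna", "n_lncnat", "n_decoys_per_stage"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimulationConfig.{name} must be >= 0")
        if not self.module_spec:
            self.module_spec = tuple(
                (self.tissues[i], 40, 1.0) for i in range(min(4, len(self.tissues)))
            )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: SequenceStore
    scaffolds: dict
    reference: list
    candidates: list
    truth: pd.DataFrame
    counts: ExpressionMatrix | None = None
    fpkm: ExpressionMatrix | None = None
    assemblies: list = field(default_factory=list)
    mirna_loci: IntervalSet | None = None
    mirna_seqs: dict = field(default_factory=dict)
    conserved: dict = field(default_factory=dict)
    homology_hits: pd.DataFrame | None = None

    def transcripts_by_id(self) -> dict[str, TranscriptModel]:
        return {t.transcript_id: t for t in self.candidates}


# ---------------------------------------------------------------------------
# Geometry generation
# ---------------------------------------------------------------------------

class _ScaffoldBuilder:
    def __init__(self, name: str, length: int, rng: np.random.Generator,
                 start_margin: int):
        self.name = name
        self.length = length
        self.seq = bytearray(
            "".join(rng.choice(_NONCODING_BASES, size=length, p=_NONCODING_PROBS)),
            "ascii",
        )
        self.cursor = start_margin

    def paste(self, pos: int, s: str) -> None:
        if pos < 0 or pos + len(s) > self.length:
            raise RuntimeError(
                f"placement beyond scaffold {self.name}; increase scaffold_length"
            )
        self.seq[pos : pos + len(s)] = s.encode("ascii")

    def reserve(self, span: int, end_margin: int) -> int:
        left = self.cursor
        if left + span > self.length - end_margin:
            raise RuntimeError(
                f"scaffold {self.name} exhausted; increase scaffold_length or n_scaffolds"
            )
        self.cursor = left + span
        return left


def _place_transcript(builder: _ScaffoldBuilder, left: int, strand: str,
                      exon_seqs: list[str], intron_lens: list[int],
                      rng: np.random.Generator,
                      splice_sites: bool = True) -> tuple[tuple[int, int], ...]:
    """Paste a transcript's pre-mRNA at ``left`` and return genomic exons.

    ``exon_seqs``/``intron_lens`` are in transcript (5'->3') order; minus-strand
    transcripts are pasted reverse-complemented, so the spliced sequence read
    back from the genome equals the designed one.
    """
    if len(intron_lens) != len(exon_seqs) - 1:
        raise ValueError("need one intron fewer than exons")
    parts, exon_spans, pos = [], [], 0
    for i, es in enumerate(exon_seqs):
        exon_spans.append((pos, pos + len(es)))
        parts.append(es)
        pos += len(es)
        if i < len(intron_lens):
            ilen = intron_lens[i]
            if ilen < 8:
                raise ValueError("introns must be >= 8 nt")
            iseq = "".join(rng.choice(_NONCODING_BASES, size=ilen, p=_NONCODING_PROBS))
            if splice_sites:
                iseq = "GT" + iseq[2:-2] + "AG"
            parts.append(iseq)
            pos += ilen
    pre = "".join(parts)
    total = len(pre)
    if strand == "+":
        builder.paste(left, pre)
        exons = tuple((left + s, left + e) for s, e in exon_spans)
    else:
        builder.paste(left, reverse_complement(pre))
        exons = tuple(sorted((left + total - e, left + total - s) for s, e in exon_spans))
    return exons


def _split_exons(rng: np.random.Generator, seq: str, n_exons: int,
                 min_exon: int = 80, first_exon_min: int | None = None) -> list[str]:
    """Cut a spliced sequence into n_exons pieces, each >= min_exon (the first
    >= first_exon_min when given), shrinking n_exons if the sequence is short."""
    length = len(seq)
    first_min = first_exon_min or min_exon
    while n_exons > 2 and first_min + (n_exons - 1) * min_exon > length:
        n_exons -= 1
    if first_min + (n_exons - 1) * min_exon > length:
        n_exons = 2 if length >= first_min + min_exon else 1
    mins = [first_min] + [min_exon] * (n_exons - 1)
    extra = length - sum(mins)
    alloc = rng.multinomial(extra, np.full(n_exons, 1.0 / n_exons)) if n_exons > 1 else [extra]
    lens = [m + int(a) for m, a in zip(mins, alloc)]
    pieces, pos = [], 0
    for ln in lens:
        pieces.append(seq[pos:pos + ln])
        pos += ln
    pieces[-1] += seq[pos:]
    return [p for p in pieces if p]


def generate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Genome, annotation, candidates, expression, assemblies, interactions
    and the truth manifest — the complete synthetic study, seed-deterministic."""
    rng = np.random.default_rng(cfg.seed)
    builders = [
        _ScaffoldBuilder(f"scaffold_{i + 1:02d}", cfg.scaffold_length, rng,
                         start_margin=cfg.end_margin + 600)
        for i in range(cfg.n_scaffolds)
    ]
    truth_rows: list[dict] = []
    reference: list[TranscriptModel] = []
    candidates: list[TranscriptModel] = []

    def truth_row(t: TranscriptModel, role: str, decoy_stage: int = 0) -> dict:
        row = {
            "transcript_id": t.transcript_id, "locus_id": t.locus_id,
            "scaffold": t.scaffold, "strand": t.strand, "role": role,
            "decoy_stage": decoy_stage, "spliced_length": t.spliced_length,
            "specificity_tissue": "ubiquitous", "sex_biased": False,
            "sex_direction": "none", "module": "none",
            "precursor_mirna": "none", "mre_mirna": "none",
            "mre_type": "none", "mre_offset": -1,
        }
        truth_rows.append(row)
        return row

    n_hosts_nat = cfg.n_lncnat + cfg.n_decoys_per_stage  # NAT hosts + stage-1 hosts
    if cfg.n_mrna < cfg.n_ilncrna + n_hosts_nat:
        raise ValueError("n_mrna too small to host all intronic/antisense placements")

    # ---- pass A: protein-coding mRNAs --------------------------------------
    mrnas: list[dict] = []
    for i in range(cfg.n_mrna):
        b = builders[i % len(builders)]
        is_ilnc_host = i < cfg.n_ilncrna
        is_nat_host = cfg.n_ilncrna <= i < cfg.n_ilncrna + n_hosts_nat
        strand = "+" if is_nat_host else ("+" if rng.random() < 0.5 else "-")
        aa = int(rng.integers(150, 351))
        orf = random_coding_orf(rng, aa)
        utr5 = random_noncoding(rng, int(rng.integers(30, 81)), max_orf_aa=None)
        utr3 = random_noncoding(rng, int(rng.integers(40, 121)), max_orf_aa=None)
        spliced = utr5 + orf + utr3
        n_exons = int(rng.integers(3, 7))
        exon_seqs = _split_exons(rng, spliced, n_exons,
                                 first_exon_min=220 if is_nat_host else None)
        intron_lens = [int(rng.integers(120, 401)) for _ in range(len(exon_seqs) - 1)]
        if is_ilnc_host:
            intron_lens[0] = 2600
        span = sum(len(e) for e in exon_seqs) + sum(intron_lens)
        pre_gap = 1100 if is_nat_host else 0
        left = b.reserve(pre_gap + span + int(rng.integers(400, 1200)), cfg.end_margin)
        gene_left = left + pre_gap
        exons = _place_transcript(b, gene_left, strand, exon_seqs, intron_lens, rng)
        tid = f"MRNA_{i + 1:04d}"
        t = TranscriptModel(tid, f"MLOC_{i + 1:04d}", b.name, strand, exons,
                            attributes={"coverage": float(np.round(rng.uniform(5, 40), 2))})
        reference.append(t)
        candidates.append(t)
        truth_row(t, "mRNA")
        mrnas.append({"model": t, "builder": b, "nat_slot": left if is_nat_host else None,
                      "long_intron": t.introns[0] if is_ilnc_host and strand == "+" else
                                     (t.introns[-1] if is_ilnc_host else None)})

    # ---- clean lncRNAs ------------------------------------------------------
    lnc_counter = 0

    def next_lnc_id() -> tuple[str, str]:
        nonlocal lnc_counter
        lnc_counter += 1
        return f"LNC_{lnc_counter:04d}", f"LLOC_{lnc_counter:04d}"

    def make_linc_like(b: _ScaffoldBuilder, left: int | None = None,
                       n_exons: int | None = None) -> tuple[tuple, str, _ScaffoldBuilder]:
        n_exons = n_exons or int(rng.integers(2, 5))
        exon_lens = [int(rng.integers(120, 401)) for _ in range(n_exons)]
        intron_lens = [int(rng.integers(150, 601)) for _ in range(n_exons - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        spliced = random_noncoding(rng, sum(exon_lens), max_orf_aa=100)
        exon_seqs = []
        pos = 0
        for el in exon_lens:
            exon_seqs.append(spliced[pos:pos + el])
            pos += el
        span = sum(exon_lens) + sum(intron_lens)
        if left is None:
            left = b.reserve(span + int(rng.integers(400, 1200)), cfg.end_margin)
        exons = _place_transcript(b, left, strand, exon_seqs, intron_lens, rng)
        return exons, strand, b

    lincs: list[TranscriptModel] = []
    for i in range(cfg.n_lincrna):
        b = builders[i % len(builders)]
        exons, strand, b = make_linc_like(b)
        tid, lid = next_lnc_id()
        t = TranscriptModel(tid, lid, b.name, strand, exons,
                            attributes={"coverage": float(np.round(rng.uniform(2, 40), 2))})
        candidates.append(t)
        truth_row(t, "lincRNA")
        lincs.append(t)

    for i in range(cfg.n_ilncrna):
        host = mrnas[i]
        b = host["builder"]
        intron = host["long_intron"]
        exon_lens = [int(rng.integers(150, 221)), int(rng.integers(150, 221))]
        intron_len = int(rng.integers(120, 201))
        span = sum(exon_lens) + intron_len
        left = intron[0] + 50 + int(rng.integers(0, max(1, intron[1] - intron[0] - span - 100)))
        strand = "+" if rng.random() < 0.5 else "-"
        spliced = random_noncoding(rng, sum(exon_lens), max_orf_aa=100)
        exons = _place_transcript(
            b, left, strand, [spliced[:exon_lens[0]], spliced[exon_lens[0]:]],
            [intron_len], rng)
        tid, lid = next_lnc_id()
        t = TranscriptModel(tid, lid, b.name, strand, exons,
                            attributes={"coverage": float(np.round(rng.uniform(2, 40), 2))})
        candidates.append(t)
        truth_row(t, "ilncRNA")

    def make_antisense(host: dict, same_strand: bool) -> TranscriptModel:
        """Two-exon transcript: one exon inside the host's first genomic exon,
        one in the reserved gap upstream of the gene."""
        hm: TranscriptModel = host["model"]
        b: _ScaffoldBuilder = host["builder"]
        gstart = hm.start
        exon_a = (gstart + 20, gstart + 180)  # inside host exon 1 (>= 220 nt)
        slot = host["nat_slot"]
        exon_b = (slot + 100, slot + 100 + int(rng.integers(250, 401)))
        # overwrite only the outside exon; the overlap exon keeps host content
        for _ in range(1000):
            bseq = "".join(rng.choice(_NONCODING_BASES, size=exon_b[1] - exon_b[0],
                                      p=_NONCODING_PROBS))
            b.paste(exon_b[0], bseq)
            strand = hm.strand if same_strand else ("-" if hm.strand == "+" else "+")
            exons = tuple(sorted([exon_a, exon_b]))
            seq_parts = "".join(builder_seq(b, s, e) for s, e in exons)
            spliced = seq_parts if strand == "+" else reverse_complement(seq_parts)
            if find_max_orf(spliced)[0] <= 100:
                return TranscriptModel("", "", b.name, strand, exons)
        raise RuntimeError("could not draw an antisense transcript with ORF <= 100 aa")

    def builder_seq(b: _ScaffoldBuilder, s: int, e: int) -> str:
        return b.seq[s:e].decode("ascii")

    for i in range(cfg.n_lncnat):
        host = mrnas[cfg.n_ilncrna + i]
        t0 = make_antisense(host, same_strand=False)
        tid, lid = next_lnc_id()
        t = TranscriptModel(tid, lid, t0.scaffold, t0.strand, t0.exons,
                            attributes={"coverage": float(np.round(rng.uniform(2, 40), 2))})
        candidates.append(t)
        truth_row(t, "lncNAT")

    # ---- decoys -------------------------------------------------------------
    def add_decoy(t: TranscriptModel, stage: int) -> None:
        candidates.append(t)
        truth_row(t, "decoy", decoy_stage=stage)

    for i in range(cfg.n_decoys_per_stage):  # stage 1: sense-exonic overlap
        host = mrnas[cfg.n_ilncrna + cfg.n_lncnat + i]
        t0 = make_antisense(host, same_strand=True)
        tid = f"DECOY_S1_{i + 1:03d}"
        add_decoy(TranscriptModel(tid, tid, t0.scaffold, t0.strand, t0.exons,
                                  attributes={"coverage": float(np.round(rng.uniform(2, 40), 2))}),
                  stage=1)

    for i in range(cfg.n_decoys_per_stage):  # stage 2: short / single-exon / low cov / low FPKM
        b = builders[i % len(builders)]
        subtype = ("short", "single_exon", "low_cov", "low_fpkm")[i % 4]
        tid = f"DECOY_S2_{i + 1:03d}"
        cov = float(np.round(rng.uniform(2, 40), 2))
        if subtype == "short":
            strand = "+" if rng.random() < 0.5 else "-"
            left = b.reserve(400 + 600, cfg.end_margin)
            seq = random_noncoding(rng, 160, max_orf_aa=None)
            exons = _place_transcript(b, left, strand, [seq[:80], seq[80:]], [200], rng)
        elif subtype == "single_exon":
            strand = "+" if rng.random() < 0.5 else "-"
            left = b.reserve(600 + 600, cfg.end_margin)
            seq = random_noncoding(rng, 600, max_orf_aa=100)
            exons = _place_transcript(b, left, strand, [seq], [], rng)
        else:
            exons, strand, b = make_linc_like(b)
            if subtype == "low_cov":
                cov = float(np.round(rng.uniform(0.2, 0.5), 2))
        t = TranscriptModel(tid, tid, b.name, strand, exons,
                            attributes={"coverage": cov, "subtype": subtype})
        add_decoy(t, stage=2)

    for i in range(cfg.n_decoys_per_stage):  # stage 3: ORF 110-200 aa
        b = builders[i % len(builders)]
        aa = int(rng.integers(110, 201))
        spliced = (random_noncoding(rng, 30, max_orf_aa=None)
                   + random_coding_orf(rng, aa)
                   + random_noncoding(rng, 30, max_orf_aa=None))
        half = len(spliced) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        left = b.reserve(len(spliced) + 300 + 600, cfg.end_margin)
        exons = _place_transcript(b, left, strand, [spliced[:half], spliced[half:]],
                                  [300], rng)
        tid = f"DECOY_S3_{i + 1:03d}"
        add_decoy(TranscriptModel(tid, tid, b.name, strand, exons,
                                  attributes={"coverage": float(np.round(rng.uniform(2, 40), 2))}),
                  stage=3)

    for i in range(cfg.n_decoys_per_stage):  # stage 4: coding-like, ORF <= 100 aa
        b = builders[i % len(builders)]
        aa = int(rng.integers(90, 100))
        spliced = (random_noncoding(rng, 20, max_orf_aa=None)
                   + random_coding_orf(rng, aa)
                   + random_noncoding(rng, 20, max_orf_aa=None))
        if find_max_orf(spliced)[0] > 100:  # UTR could extend the frame; redraw once
            spliced = "CCC" + random_coding_orf(rng, aa) + "CCC" * 7
        half = len(spliced) // 2
        strand = "+" if rng.random() < 0.5 else "-"
        left = b.reserve(len(spliced) + 250 + 600, cfg.end_margin)
        exons = _place_transcript(b, left, strand, [spliced[:half], spliced[half:]],
                                  [250], rng)
        tid = f"DECOY_S4_{i + 1:03d}"
        add_decoy(TranscriptModel(tid, tid, b.name, strand, exons,
                                  attributes={"coverage": float(np.round(rng.uniform(2, 40), 2))}),
                  stage=4)

    for i in range(cfg.n_decoys_per_stage):  # stage 5: homology-hit-listed
        b = builders[i % len(builders)]
        exons, strand, b = make_linc_like(b)
        tid = f"DECOY_S5_{i + 1:03d}"
        add_decoy(TranscriptModel(tid, tid, b.name, strand, exons,
                                  attributes={"coverage": float(np.round(rng.uniform(2, 40), 2))}),
                  stage=5)

    for i in range(cfg.n_decoys_per_stage):  # stage 6: within 2 kb of a scaffold end
        b = builders[i % len(builders)]
        left = 300 + (i // len(builders)) * 1800
        exon_lens = [int(rng.integers(120, 200)), int(rng.integers(120, 200))]
        spliced = random_noncoding(rng, sum(exon_lens), max_orf_aa=100)
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _place_transcript(b, left, strand,
                                  [spliced[:exon_lens[0]], spliced[exon_lens[0]:]],
                                  [150], rng)
        tid = f"DECOY_S6_{i + 1:03d}"
        add_decoy(TranscriptModel(tid, tid, b.name, strand, exons,
                                  attributes={"coverage": float(np.round(rng.uniform(2, 40), 2))}),
                  stage=6)

    genome = SequenceStore()
    for b in builders:
        genome[b.name] = b.seq.decode("ascii")
    scaffolds = {b.name: b.length for b in builders}
    truth = pd.DataFrame(truth_rows).set_index("transcript_id")

    ds = SimulatedDataset(cfg, genome, scaffolds, reference, candidates, truth)

    _assign_conditions(ds, rng)
    simulate_expression(ds, rng)
    simulate_assembly_replicates(ds, rng)
    plant_interactions(ds, rng)
    _assert_geometry(ds)
    return ds


def _assign_conditions(ds: SimulatedDataset, rng: np.random.Generator) -> None:
    """Plant tissue specificity, sex bias and module membership in the truth."""
    cfg = ds.config
    truth = ds.truth
    clean_lnc = truth.index[truth["role"].isin(["lincRNA", "ilncRNA", "lncNAT"])]
    n_specific = int(round(cfg.specific_fraction * len(clean_lnc)))
    specific_ids = list(clean_lnc[:n_specific])
    for j, tid in enumerate(specific_ids):
        truth.loc[tid, "specificity_tissue"] = cfg.tissues[j % len(cfg.tissues)]

    # module members: interleave ubiquitous mRNAs and lncRNAs so modules mix both
    ubi_mrna = [tid for tid in truth.index if truth.loc[tid, "role"] == "mRNA"]
    ubi_lnc = [tid for tid in clean_lnc
               if truth.loc[tid, "specificity_tissue"] == "ubiquitous"]
    ubiquitous = []
    for i in range(max(len(ubi_mrna), len(ubi_lnc))):
        if i < len(ubi_mrna):
            ubiquitous.append(ubi_mrna[i])
        if i < len(ubi_lnc):
            ubiquitous.append(ubi_lnc[i])
    pos = 0
    for m, (tissue, n_members, _strength) in enumerate(cfg.module_spec):
        members = ubiquitous[pos:pos + n_members]
        pos += n_members
        for tid in members:
            truth.loc[tid, "module"] = f"sim_module_{m + 1}"

    # sex bias on ubiquitous, non-module transcripts (keeps module structure clean)
    eligible = [tid for tid in ubiquitous if truth.loc[tid, "module"] == "none"]
    n_biased = int(round(cfg.sex_biased_fraction * len(eligible)))
    for j, tid in enumerate(eligible[:n_biased]):
        truth.loc[tid, "sex_biased"] = True
        truth.loc[tid, "sex_direction"] = "F" if j % 2 == 0 else "M"


def simulate_expression(ds: SimulatedDataset, rng: np.random.Generator) -> None:
    """Negative-binomial counts and FPKM for tissue x sex samples.

    Per-transcript log2 baseline; point-mass profiles for tissue-specific
    transcripts; shared latent per-sample factors within modules; a 4-fold
    multiplier for the favored sex of sex-biased transcripts;
    FPKM = counts * 1e9 / (length * library_size).
    """
    cfg = ds.config
    truth = ds.truth
    tissues = list(cfg.tissues)
    samples = pd.DataFrame(
        [{"sample_id": f"{t}_{s}", "tissue": t, "sex": s, "library_size": cfg.library_size}
         for t in tissues for s in ("F", "M")]
    ).set_index("sample_id")
    n_s = len(samples)
    ids = list(truth.index)
    lengths = truth["spliced_length"].to_numpy(dtype=float)

    base_log2 = np.where(truth["role"].to_numpy() == "mRNA",
                         rng.normal(6.0, 1.0, size=len(ids)),
                         rng.normal(5.0, 1.0, size=len(ids)))
    base_log2 = np.clip(base_log2, 4.0, None)
    log2mu = np.tile(base_log2[:, None], (1, n_s))

    tissue_of_sample = samples["tissue"].to_numpy()
    sex_of_sample = samples["sex"].to_numpy()

    module_factor = {}
    for m, (tissue, _n, strength) in enumerate(cfg.module_spec):
        z = 2.0 * (tissue_of_sample == tissue) + rng.normal(0.0, 0.4, size=n_s)
        module_factor[f"sim_module_{m + 1}"] = strength * z

    by_id = ds.transcripts_by_id()
    mask_zero = np.zeros((len(ids), n_s), dtype=bool)
    for i, tid in enumerate(ids):
        row = truth.loc[tid]
        spec = row["specificity_tissue"]
        if spec != "ubiquitous":
            mask_zero[i] = tissue_of_sample != spec
        if row["module"] != "none":
            log2mu[i] += module_factor[row["module"]]
        if row["sex_biased"]:
            fav = row["sex_direction"]
            log2mu[i, sex_of_sample == fav] += np.log2(cfg.sex_fold_change)
        if row["role"] == "decoy" and row["decoy_stage"] == 2:
            if by_id[tid].attributes.get("subtype") == "low_fpkm":
                mask_zero[i] = True

    mu = np.power(2.0, log2mu)
    mu[mask_zero] = 0.0
    disp = cfg.nb_dispersion
    shape = 1.0 / disp
    lam = np.where(mu > 0, rng.gamma(shape, 1.0, size=mu.shape) * mu * disp, 0.0)
    counts = rng.poisson(lam)
    fpkm = counts * 1e9 / (lengths[:, None] * cfg.library_size)

    ds.counts = ExpressionMatrix(
        pd.DataFrame(counts, index=ids, columns=samples.index), samples, kind="counts")
    ds.fpkm = ExpressionMatrix(
        pd.DataFrame(fpkm, index=ids, columns=samples.index), samples, kind="fpkm")


def simulate_assembly_replicates(ds: SimulatedDataset, rng: np.random.Generator) -> None:
    """Pseudo-assembler x tissue transcript sets with jittered terminal ends.

    Inclusion probability follows expression in the tissue; intron coordinates
    are never jittered, so intron-chain identity is preserved; a configurable
    fraction of transcripts appears in exactly one (assembler, tissue) run.
    """
    cfg = ds.config
    fpkm_by_tissue = ds.fpkm.tissue_means()
    ids = list(ds.truth.index)
    singleton = set(
        tid for tid in ids
        if rng.random() < cfg.singleton_fraction and ds.truth.loc[tid, "role"] != "decoy"
    )
    by_id = ds.transcripts_by_id()
    assemblies = []
    for assembler in cfg.assemblers:
        for tissue in cfg.tissues:
            models = []
            for tid in ids:
                t = by_id[tid]
                expressed = fpkm_by_tissue.loc[tid, tissue] > 0.5
                if tid in singleton:
                    best = fpkm_by_tissue.loc[tid].idxmax()
                    include = (assembler == cfg.assemblers[0] and tissue == best)
                    _ = rng.random()  # keep the stream aligned across branches
                else:
                    p = cfg.inclusion_prob_expressed if expressed else cfg.inclusion_prob_silent
                    include = rng.random() < p
                if not include:
                    continue
                exons = list(t.exons)
                s0, e0 = exons[0]
                d = int(rng.integers(-50, 51))
                exons[0] = (min(max(0, s0 + d), e0 - 30), e0)
                s1, e1 = exons[-1]
                d = int(rng.integers(-50, 51))
                exons[-1] = (s1, max(min(ds.scaffolds[t.scaffold], e1 + d), s1 + 30))
                models.append(TranscriptModel(
                    f"{tid}.{assembler[:4]}.{tissue}", tid, t.scaffold, t.strand,
                    tuple(exons), attributes=dict(t.attributes)))
            assemblies.append((assembler, tissue, models))
    ds.assemblies = assemblies


def _spliced_offset_to_genomic(t: TranscriptModel, offset: int) -> tuple[int, int]:
    """Genomic (position, direction) of a spliced-coordinate offset; direction
    +1 on the plus strand, -1 on the minus strand."""
    if t.strand == "+":
        remaining = offset
        for s, e in t.exons:
            if remaining < e - s:
                return s + remaining, 1
            remaining -= e - s
    else:
        remaining = offset
        for s, e in reversed(t.exons):
            if remaining < e - s:
                return e - 1 - remaining, -1
            remaining -= e - s
    raise ValueError("offset beyond spliced length")


def _paste_spliced(genome_arrays: dict[str, bytearray], t: TranscriptModel,
                   offset: int, s: str) -> None:
    """Write ``s`` into the genome at spliced offset (must fit in one exon)."""
    pos, direction = _spliced_offset_to_genomic(t, offset)
    if direction == 1:
        genome_arrays[t.scaffold][pos : pos + len(s)] = s.encode("ascii")
    else:
        rc = reverse_complement(s)
        genome_arrays[t.scaffold][pos - len(s) + 1 : pos + 1] = rc.encode("ascii")


def plant_interactions(ds: SimulatedDataset, rng: np.random.Generator) -> None:
    """miRNA loci (precursor + antisense controls), seed sites in conserved
    windows, and the homology-hit table for stage-5 decoys."""
    cfg = ds.config
    truth = ds.truth
    arrays = {name: bytearray(seq, "ascii") for name, seq in ds.genome.items()}
    by_id = ds.transcripts_by_id()

    lincs = [tid for tid in truth.index if truth.loc[tid, "role"] == "lincRNA"]
    mirna_loci = IntervalSet()
    mirna_seqs: dict[str, str] = {}
    mirna_names = [f"sim-miR-{i + 1}" for i in range(cfg.n_mirnas)]

    def mature_from_genome(t: TranscriptModel, antisense: bool = False) -> tuple[str, int, int, str]:
        exon = max(t.exons, key=lambda x: x[1] - x[0])
        start = exon[0] + 5
        end = start + 22
        strand = t.strand
        if antisense:
            strand = "-" if strand == "+" else "+"
        seq = ds.genome[t.scaffold][start:end]
        if strand == "-":
            seq = reverse_complement(seq)
        return seq, start, end, strand

    k = 0
    for i in range(cfg.n_precursors):
        tid = lincs[i]
        t = by_id[tid]
        seq, start, end, strand = mature_from_genome(t)
        name = mirna_names[k]; k += 1
        mirna_loci.add(t.scaffold, start, end, strand, name)
        mirna_seqs[name] = seq.replace("T", "U")
        truth.loc[tid, "precursor_mirna"] = name
    for i in range(cfg.n_antisense_mirnas):
        tid = lincs[cfg.n_precursors + i]
        t = by_id[tid]
        seq, start, end, strand = mature_from_genome(t, antisense=True)
        name = mirna_names[k]; k += 1
        mirna_loci.add(t.scaffold, start, end, strand, name)
        mirna_seqs[name] = seq.replace("T", "U")
    while k < cfg.n_mirnas:  # free miRNAs on intergenic background
        b_name = sorted(ds.scaffolds)[k % len(ds.scaffolds)]
        start = ds.scaffolds[b_name] - cfg.end_margin + 100 + 30 * k
        name = mirna_names[k]
        mirna_loci.add(b_name, start, start + 22, "+", name)
        mirna_seqs[name] = ds.genome[b_name][start:start + 22].replace("T", "U")
        k += 1

    # seed sites inside conserved windows of clean (non-precursor) lincRNAs
    site_types = ("8mer", "7mer-m8", "7mer-A1", "6mer")
    conserved: dict[str, list[tuple[int, int]]] = {}
    start_pool = lincs[cfg.n_precursors + cfg.n_antisense_mirnas:]
    planted = start_pool[:cfg.n_mre_lncrnas]
    for j, tid in enumerate(planted):
        t = by_id[tid]
        mirna = mirna_names[j % cfg.n_mirnas]
        site_type = site_types[j % 4]
        mseq = mirna_seqs[mirna].replace("U", "T")
        core = reverse_complement(mseq[1:7])
        m8 = reverse_complement(mseq[7])
        if site_type == "8mer":
            site = m8 + core + "A"
        elif site_type == "7mer-m8":
            site = m8 + core
        elif site_type == "7mer-A1":
            site = core + "A"
        else:
            site = core
        # place inside the first exon (transcript orientation), with flank control
        first_len = (t.exons[0][1] - t.exons[0][0]) if t.strand == "+" else \
                    (t.exons[-1][1] - t.exons[-1][0])
        offset = 20 + int(rng.integers(0, max(1, first_len - len(site) - 45)))
        blocker = "C" if m8 != "C" else "G"
        pre = blocker if site_type in ("7mer-A1", "6mer") else ""
        post = "C" if site_type in ("7mer-m8", "6mer") else ""
        _paste_spliced(arrays, t, offset - len(pre), pre + site + post)
        window = (max(0, offset - 15), min(t.spliced_length, offset + len(site) + 15))
        conserved[tid] = [window]
        truth.loc[tid, "mre_mirna"] = mirna
        truth.loc[tid, "mre_type"] = site_type
        truth.loc[tid, "mre_offset"] = offset
    # a few conserved windows without planted sites
    for tid in start_pool[cfg.n_mre_lncrnas:cfg.n_mre_lncrnas + 3]:
        conserved[tid] = [(10, min(by_id[tid].spliced_length, 140))]

    for name in arrays:
        ds.genome[name] = arrays[name].decode("ascii")
    ds.mirna_loci = mirna_loci
    ds.mirna_seqs = mirna_seqs
    ds.conserved = conserved

    rows = [{"query_id": tid, "subject_id": f"sp|P{10000 + i}", "evalue": 1e-10}
            for i, tid in enumerate(truth.index[(truth["role"] == "decoy")
                                                & (truth["decoy_stage"] == 5)])]
    rows += [{"query_id": tid, "subject_id": "sp|P99999", "evalue": 1e-3}
             for tid in lincs[:2]]  # weak hits below the filter threshold
    ds.homology_hits = pd.DataFrame(rows, columns=["query_id", "subject_id", "evalue"])


def _assert_geometry(ds: SimulatedDataset) -> None:
    """Post-generation invariants: planted classes and decoy stages hold."""
    from .annotation_io import spliced_sequence

    by_id = ds.transcripts_by_id()
    for tid, row in ds.truth.iterrows():
        t = by_id[tid]
        if row["role"] in ("lincRNA", "ilncRNA", "lncNAT"):
            seq = spliced_sequence(t, ds.genome)
            assert find_max_orf(seq)[0] <= 100, f"{tid}: planted lncRNA has long ORF"
            assert t.spliced_length >= 200 and t.n_exons >= 2
        if row["role"] == "decoy" and row["decoy_stage"] == 6:
            margin = ds.config.end_margin
            length = ds.scaffolds[t.scaffold]
            assert t.start < margin or length - t.end < margin
        if row["role"] == "decoy" and row["decoy_stage"] == 3:
            assert find_max_orf(spliced_sequence(t, ds.genome))[0] > 100


# ---------------------------------------------------------------------------
# Truth I/O and dataset writing
# ---------------------------------------------------------------------------

def write_truth(truth: pd.DataFrame, path) -> None:
    truth.sort_index().to_csv(path, sep="\t")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write every artifact of the simulated study under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.genome, outdir / "genome.fa")
    with open(outdir / "scaffolds.tsv", "w") as fh:
        for name in sorted(ds.scaffolds):
            fh.write(f"{name}\t{ds.scaffolds[name]}\n")
    write_gtf(ds.reference, outdir / "ref.gtf")
    write_gtf(ds.candidates, outdir / "candidates.gtf")
    asm_dir = outdir / "assemblies"
    asm_dir.mkdir(exist_ok=True)
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("assembler\ttissue\tgtf_path\n")
        for assembler, tissue, models in ds.assemblies:
            path = asm_dir / f"{assembler}_{tissue}.gtf"
            write_gtf(models, path)
            fh.write(f"{assembler}\t{tissue}\t{path.relative_to(outdir)}\n")
    ds.counts.write(outdir / "counts.tsv", outdir / "samples.tsv")
    ds.fpkm.write(outdir / "fpkm.tsv")
    with open(outdir / "mirna.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for scaffold, s, e, strand, name in ds.mirna_loci:
            fh.write(f"{scaffold}\t.\tmiRNA\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                     f"ID={name};Name={name}\n")
    with open(outdir / "mirna.fa", "w") as fh:
        for name in sorted(ds.mirna_seqs):
            fh.write(f">{name}\n{ds.mirna_seqs[name]}\n")
    with open(outdir / "conserved.tsv", "w") as fh:
        fh.write("transcript_id\tstart\tend\n")
        for tid in sorted(ds.conserved):
            for s, e in ds.conserved[tid]:
                fh.write(f"{tid}\t{s}\t{e}\n")
    ds.homology_hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    write_truth(ds.truth, outdir / "truth.tsv")


# ---------------------------------------------------------------------------
# Focused simulators for calibration studies
# ---------------------------------------------------------------------------

def simulate_block_expression(n_transcripts: int = 200, n_samples: int = 40,
                              n_blocks: int = 4, shift: float = 3.0,
                              within_cor: float = 0.9, seed: int = 1
                              ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Planted-block design for module recovery: each block shares a latent
    factor elevated in its own samples; member profiles correlate ~within_cor.

    Returns (expression, true block labels, binary sample traits).
    """
    rng = np.random.default_rng(seed)
    per_block = n_transcripts // n_blocks
    samples = [f"s{i + 1:02d}" for i in range(n_samples)]
    block_of_sample = np.repeat(np.arange(n_blocks), n_samples // n_blocks)
    rows, labels = [], []
    traits = pd.DataFrame(
        {f"trait_block{b + 1}": (block_of_sample == b).astype(int) for b in range(n_blocks)},
        index=samples)
    for b in range(n_blocks):
        f = shift * (block_of_sample == b) + rng.normal(0, 1, size=n_samples)
        var_f = f.var()
        sigma = np.sqrt(var_f * (1.0 / within_cor - 1.0))
        for j in range(per_block):
            rows.append(f + rng.normal(0, sigma, size=n_samples))
            labels.append(f"block{b + 1}")
    leftover = n_transcripts - per_block * n_blocks
    for j in range(leftover):
        rows.append(rng.normal(0, 1, size=n_samples))
        labels.append("noise")
    ids = [f"g{i + 1:04d}" for i in range(len(rows))]
    expr = pd.DataFrame(np.array(rows), index=ids, columns=samples)
    return expr, pd.Series(labels, index=ids), traits


def simulate_sex_counts(n_transcripts: int, mean_count: float, fold_change: float,
                        dispersion: float, library_size: float, seed: int,
                        biased_fraction: float = 0.0
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(x_f, x_m, biased flags) for sex-bias calibration studies.

    Counts are negative-binomial with the given dispersion, or exact Poisson
    when ``dispersion == 0`` — the latter is the sampling model the exact
    binomial test assumes (library-size-proportional random sampling), i.e.
    the null under which the test's type-I error is defined.  An optional
    fold-change multiplies the female mean of the biased transcripts.
    """
    rng = np.random.default_rng(seed)
    base = np.full(n_transcripts, mean_count, dtype=float)
    biased = np.zeros(n_transcripts, dtype=bool)
    n_biased = int(round(biased_fraction * n_transcripts))
    biased[:n_biased] = True
    mu_f = np.where(biased, base * fold_change, base)
    mu_m = base

    def draw(mu):
        if dispersion == 0:
            return rng.poisson(mu)
        lam = rng.gamma(1.0 / dispersion, 1.0, size=mu.shape) * mu * dispersion
        return rng.poisson(lam)

    return draw(mu_f), draw(mu_m), biased
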