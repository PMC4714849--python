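"""miRNA precursor detection and canonical seed-site (MRE) scanning.

A lncRNA locus is a candidate miRNA precursor when a mature miRNA interval
overlaps its genomic span on the same strand.  A lncRNA is a candidate
competing endogenous RNA (ceRNA) when its conserved regions harbor seed-
complementary miRNA response elements: the scanner reports canonical 6mer,
7mer-A1, 7mer-m8 and 8mer sites (the shared core of the miRanda/PITA/RNAhybrid
family of predictors; thermodynamic scoring is deliberately out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation_io import IntervalSet, TranscriptModel, reverse_complement

__all__ = [
    "MREHit",
    "precursor_overlap",
    "scan_mre_sites",
    "cerna_filter",
    "SITE_TYPES",
]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


@dataclass(frozen=True)
class MREHit:
    """One seed-complementary site on a spliced lncRNA sequence."""

    lncrna_id: str
    mirna_id: str
    start: int  # 0-based half-open on the spliced sequence
    end: int
    site_type: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        expected = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[self.site_type]
        if self.end - self.start != expected:
            raise ValueError(f"{self.site_type} site must span {expected} nt")


def precursor_overlap(lncrnas: list[TranscriptModel],
                      mirna_loci: IntervalSet) -> pd.DataFrame:
    """Pairs (lncRNA locus, miRNA) with >= 1 bp same-strand span overlap.

    The locus span is the union of its isoforms' spans.  ``exonic`` is True
    when the mature interval is fully covered by the locus's exon union (a
    genuine pre-miRNA hairpin is exonic).  Strandless miRNA records are
    rejected.
    """
    loci: dict[str, dict] = {}
    for t in lncrnas:
        rec = loci.setdefault(t.locus_id, {
            "scaffold": t.scaffold, "strand": t.strand,
            "start": t.start, "end": t.end, "exons": [],
            "transcripts": [],
        })
        if rec["scaffold"] != t.scaffold or rec["strand"] != t.strand:
            raise ValueError(f"locus {t.locus_id!r}: isoforms disagree on scaffold/strand")
        rec["start"] = min(rec["start"], t.start)
        rec["end"] = max(rec["end"], t.end)
        rec["exons"].extend(t.exons)
        rec["transcripts"].append(t.transcript_id)

    rows = []
    for scaffold, ms, me, strand, name in mirna_loci:
        if strand not in ("+", "-"):
            raise ValueError(f"miRNA record {name!r} on {scaffold} lacks strand")
        for locus_id in sorted(loci):
            rec = loci[locus_id]
            if rec["scaffold"] != scaffold or rec["strand"] != strand:
                continue
            if ms < rec["end"] and rec["start"] < me:
                # exonic flag: mature interval fully covered by the exon union
                exonic = _covered_by_union(rec["exons"], ms, me)
                rows.append({
                    "locus_id": locus_id, "mirna_id": name,
                    "scaffold": scaffold, "strand": strand,
                    "mirna_start": ms, "mirna_end": me,
                    "exonic": exonic,
                    "transcript_ids": ",".join(sorted(rec["transcripts"])),
                })
    return pd.DataFrame(rows, columns=["locus_id", "mirna_id", "scaffold", "strand",
                                       "mirna_start", "mirna_end", "exonic",
                                       "transcript_ids"])


def _covered_by_union(exons: list[tuple[int, int]], start: int, end: int) -> bool:
    ivs = sorted((max(s, start), min(e, end)) for s, e in exons if min(e, end) > max(s, start))
    pos = start
    for s, e in ivs:
        if s > pos:
            return False
        pos = max(pos, e)
    return pos >= end


def _rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def scan_mre_sites(lnc_seq: str, mirna_seq: str, lncrna_id: str = "",
                   mirna_id: str = "") -> list[MREHit]:
    """Canonical seed sites of ``mirna_seq`` (mature, 5'->3') on ``lnc_seq``.

    On the target read 5'->3', the seed match runs antiparallel to the miRNA:
    the reverse complement of miRNA positions 2-7 (6mer core), preceded by the
    complement of position 8 (m8 match) and/or followed by an 'A' opposite
    position 1.  Each 6mer-core occurrence is reported once at its strongest
    type: 8mer > 7mer-m8 > 7mer-A1 > 6mer.
    """
    mirna = _rna_to_dna(mirna_seq)
    if len(mirna) < 19:
        raise ValueError(f"mature miRNA must be >= 19 nt, got {len(mirna)}")
    lnc = _rna_to_dna(lnc_seq)
    core = reverse_complement(mirna[1:7])      # rc of positions 2-7
    m8 = reverse_complement(mirna[7])          # complement of position 8
    hits = []
    i = lnc.find(core)
    while i != -1:
        has_m8 = i >= 1 and lnc[i - 1] == m8
        has_a1 = i + 6 < len(lnc) and lnc[i + 6] == "A"
        if has_m8 and has_a1:
            hit = MREHit(lncrna_id, mirna_id, i - 1, i + 7, "8mer")
        elif has_m8:
            hit = MREHit(lncrna_id, mirna_id, i - 1, i + 6, "7mer-m8")
        elif has_a1:
            hit = MREHit(lncrna_id, mirna_id, i, i + 7, "7mer-A1")
        else:
            hit = MREHit(lncrna_id, mirna_id, i, i + 6, "6mer")
        hits.append(hit)
        i = lnc.find(core, i + 1)
    return hits


def cerna_filter(hits: list[MREHit], conserved_regions: dict[str, list[tuple[int, int]]],
                 min_distinct_mirnas: int = 1,
                 transcript_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Keep hits fully inside a conserved region of their lncRNA; a lncRNA is a
    ceRNA candidate when the kept hits involve >= ``min_distinct_mirnas``
    distinct miRNAs.

    ``conserved_regions`` maps transcript id -> (start, end) windows in spliced
    coordinates.  With ``transcript_lengths``, regions beyond a transcript's
    end are rejected.
    """
    if transcript_lengths is not None:
        for tid, regions in conserved_regions.items():
            length = transcript_lengths.get(tid)
            if length is None:
                continue
            for s, e in regions:
                if s < 0 or e > length:
                    raise ValueError(
                        f"conserved region ({s},{e}) outside transcript {tid!r} (len {length})"
                    )
    kept: dict[str, list[MREHit]] = {}
    for h in hits:
        for s, e in conserved_regions.get(h.lncrna_id, []):
            if s <= h.start and h.end <= e:
                kept.setdefault(h.lncrna_id, []).append(h)
                break
    rows = []
    for tid in sorted(kept):
        mirnas = sorted({h.mirna_id for h in kept[tid]})
        if len(mirnas) >= min_distinct_mirnas:
            rows.append({
                "lncrna_id": tid,
                "n_sites": len(kept[tid]),
                "n_mirnas": len(mirnas),
                "mirna_ids": ",".join(mirnas),
            })
    return pd.DataFrame(rows, columns=["lncrna_id", "n_sites", "n_mirnas", "mirna_ids"])
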