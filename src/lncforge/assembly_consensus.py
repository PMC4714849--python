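"""Consensus ("stringent transcript") selection and merging across assemblies.

A transcript observed in several (assembler, tissue) runs is trusted when its
intron chain was assembled by at least two programs or in at least two tissues;
the retained chains are then merged into a unique transcript set, collapsing
identical intron chains and grouping same-strand overlapping transcripts into
loci, the way Cuffmerge does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .annotation_io import TranscriptModel

__all__ = [
    "intron_chain_key",
    "SupportTable",
    "build_support",
    "stringent_select",
    "merge_transcripts",
]


def intron_chain_key(t: TranscriptModel) -> str:
    """Identity key of a multi-exon transcript: scaffold, strand, ordered introns.

    Transcripts differing only in their terminal exon ends share a key.
    Single-exon transcripts have no intron chain and are rejected (they are
    excluded from the identification pipeline upstream).
    """
    if t.n_exons < 2:
        raise ValueError(
            f"transcript {t.transcript_id!r}: single-exon transcripts have no intron chain"
        )
    introns = ",".join(f"{s}-{e}" for s, e in t.introns)
    return f"{t.scaffold}:{t.strand}:{introns}"


@dataclass
class SupportTable:
    """Per intron chain: the (assembler, tissue) support set and witness models."""

    chains: dict[str, dict] = field(default_factory=dict)
    n_single_exon_skipped: int = 0

    def support(self, key: str) -> frozenset[tuple[str, str]]:
        return frozenset(self.chains[key]["support"])


def build_support(assemblies: list[tuple[str, str, list[TranscriptModel]]]) -> SupportTable:
    """Union (assembler, tissue) support per intron chain across assemblies.

    Duplicate observations within one (assembler, tissue) run count once.
    Single-exon transcripts carry no chain and are skipped (counted).
    """
    if not assemblies:
        raise ValueError("no assemblies provided")
    table = SupportTable()
    for assembler, tissue, transcripts in assemblies:
        for t in transcripts:
            if t.n_exons < 2:
                table.n_single_exon_skipped += 1
                continue
            key = intron_chain_key(t)
            rec = table.chains.setdefault(key, {"support": set(), "witnesses": []})
            rec["support"].add((assembler, tissue))
            rec["witnesses"].append(t)
    return table


def _union_of_witnesses(witnesses: list[TranscriptModel]) -> TranscriptModel:
    """One representative per chain: terminal exon ends are the witness union."""
    rep = min(witnesses, key=lambda t: t.transcript_id)
    first_start = min(t.exons[0][0] for t in witnesses)
    last_end = max(t.exons[-1][1] for t in witnesses)
    exons = list(rep.exons)
    exons[0] = (first_start, exons[0][1])
    exons[-1] = (exons[-1][0], last_end)
    return TranscriptModel(
        transcript_id=rep.transcript_id,
        locus_id=rep.locus_id,
        scaffold=rep.scaffold,
        strand=rep.strand,
        exons=tuple(exons),
        attributes={},  # witness cov/FPKM dropped; expression is re-estimated downstream
        support=frozenset().union(*(t.support for t in witnesses)) or frozenset(),
    )


def stringent_select(table: SupportTable) -> list[TranscriptModel]:
    """Retain chains supported by >= 2 distinct assemblers OR >= 2 distinct tissues."""
    kept: list[TranscriptModel] = []
    for key in sorted(table.chains):
        rec = table.chains[key]
        assemblers = {a for a, _ in rec["support"]}
        tissues = {ti for _, ti in rec["support"]}
        if len(assemblers) >= 2 or len(tissues) >= 2:
            rep = _union_of_witnesses(rec["witnesses"])
            rep = TranscriptModel(
                transcript_id=rep.transcript_id, locus_id=rep.locus_id,
                scaffold=rep.scaffold, strand=rep.strand, exons=rep.exons,
                attributes=rep.attributes, support=frozenset(rec["support"]),
            )
            kept.append(rep)
    return kept


def _assign_loci(transcripts: list[TranscriptModel]) -> list[TranscriptModel]:
    """Single-linkage loci over same-strand exonic overlap (antisense never shares)."""
    n = len(transcripts)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # sweep exon intervals per (scaffold, strand)
    by_group: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for idx, t in enumerate(transcripts):
        for s, e in t.exons:
            by_group.setdefault((t.scaffold, t.strand), []).append((s, e, idx))
    for ivs in by_group.values():
        ivs.sort()
        active: list[tuple[int, int]] = []  # (end, idx)
        for s, e, idx in ivs:
            active = [(ae, ai) for ae, ai in active if ae > s]
            for _, ai in active:
                union(ai, idx)
            active.append((e, idx))

    roots = sorted({find(i) for i in range(n)},
                   key=lambda r: (transcripts[r].scaffold, transcripts[r].start))
    locus_of_root = {r: f"LOC_{k + 1:06d}" for k, r in enumerate(roots)}
    out = []
    for i, t in enumerate(transcripts):
        out.append(TranscriptModel(
            transcript_id=t.transcript_id, locus_id=locus_of_root[find(i)],
            scaffold=t.scaffold, strand=t.strand, exons=t.exons,
            attributes=dict(t.attributes), support=t.support,
        ))
    return out


def merge_transcripts(transcripts: list[TranscriptModel]) -> list[TranscriptModel]:
    """Collapse identical intron chains (terminal ends unioned) and assign loci.

    Idempotent; isoform count per locus equals the number of distinct intron
    chains whose transcripts share same-strand exonic overlap.
    """
    by_chain: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chain.setdefault(intron_chain_key(t), []).append(t)
    merged = [_union_of_witnesses(ws) for ws in by_chain.values()]
    merged.sort(key=lambda t: (t.scaffold, t.start, t.end, t.transcript_id))
    if not merged:
        return []
    return _assign_loci(merged)
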