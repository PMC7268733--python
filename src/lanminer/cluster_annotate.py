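"""Accessory-gene domain annotation, co-occurrence census, and run summaries."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from lanminer.bgc_classify import BgcCall
from lanminer.genome_io import GenomeRecord
from lanminer.hmm_profiles import HmmHit, ProfileHmm, hmm_search
from lanminer.report import MiningReport

ANNOTATION_E_CUTOFF = 1e-5


class GcError(ValueError):
    """No unambiguous bases to compute GC content over."""


@dataclass
class TailoringAnnotation:
    bgc_id: str
    per_gene: dict[str, list[HmmHit]]
    e_cutoff: float = ANNOTATION_E_CUTOFF


@dataclass(frozen=True)
class CensusRow:
    accession: str | None
    name: str
    total: int
    per_class: tuple[tuple[str, int], ...]


@dataclass
class CensusTable:
    rows: list[CensusRow] = field(default_factory=list)

    def as_tsv(self) -> str:
        classes = ("I", "II", "III", "IV", "unclassified")
        lines = ["\t".join(("accession", "name", "total") + classes)]
        for r in self.rows:
            per = dict(r.per_class)
            lines.append(
                "\t".join(
                    [r.accession or ".", r.name, str(r.total)] + [str(per.get(c, 0)) for c in classes]
                )
            )
        return "\n".join(lines) + "\n"


def annotate_genes(
    bgc: BgcCall, domain_models: Sequence[ProfileHmm], e_cutoff: float = ANNOTATION_E_CUTOFF, bgc_id: str = ""
) -> TailoringAnnotation:
    """Search every neighborhood gene against the domain models at E <= cutoff."""
    per_gene: dict[str, list[HmmHit]] = {g.locus_id: [] for g in bgc.neighborhood.genes}
    if domain_models:
        proteins = [
            (g.protein_id or g.locus_id, g.protein_seq)
            for g in bgc.neighborhood.genes
            if g.protein_seq
        ]
        hits = hmm_search(domain_models, proteins, e_cutoff=e_cutoff)
        by_protein: dict[str, list[HmmHit]] = {}
        for h in hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        for g in bgc.neighborhood.genes:
            per_gene[g.locus_id] = by_protein.get(g.protein_id or g.locus_id, [])
    return TailoringAnnotation(bgc_id=bgc_id, per_gene=per_gene, e_cutoff=e_cutoff)


def census(annotations: Sequence[TailoringAnnotation], calls: Sequence[BgcCall]) -> CensusTable:
    """Count BGCs (not genes) containing >= 1 hit of each domain, per class."""
    if len(annotations) != len(calls):
        raise ValueError("annotations and calls must be aligned")
    total: Counter[str] = Counter()
    per_class: dict[str, Counter[str]] = {}
    for ann, call in zip(annotations, calls):
        domains = {h.hmm_name for hits in ann.per_gene.values() for h in hits}
        for d in domains:
            total[d] += 1
            per_class.setdefault(d, Counter())[call.lan_class] += 1
    rows = [
        CensusRow(
            accession=None,
            name=name,
            total=n,
            per_class=tuple(sorted(per_class[name].items())),
        )
        for name, n in total.items()
    ]
    rows.sort(key=lambda r: (-r.total, r.name))
    return CensusTable(rows=rows)


def gc_content(dna: str) -> float:
    """(G+C) / (A+C+G+T); N is excluded from both numerator and denominator."""
    dna = dna.upper()
    gc = dna.count("G") + dna.count("C")
    atgc = gc + dna.count("A") + dna.count("T")
    if atgc == 0:
        raise GcError("sequence has no unambiguous bases")
    return gc / atgc


def _phylum(record: GenomeRecord) -> str:
    return record.lineage[1] if len(record.lineage) >= 2 else "unknown"


def summarize(
    calls: Sequence[BgcCall],
    precursors: Sequence,
    records: Sequence[GenomeRecord],
    bgc_ids: Sequence[str] | None = None,
    precursor_bgc_ids: Sequence[str] | None = None,
) -> MiningReport:
    """Aggregate per-class and per-phylum tallies, GG-leader fraction,
    (bgc GC, genome GC) pairs, and the precursors-per-BGC histogram.

    When precursor_bgc_ids is omitted, each precursor is mapped to the first
    BGC whose neighborhood span contains its ORF on the same record.
    """
    if bgc_ids is None:
        bgc_ids = [f"bgc{i}" for i in range(len(calls))]
    by_record = {r.record_id: r for r in records}

    if precursor_bgc_ids is None:
        precursor_bgc_ids = []
        for p in precursors:
            owner = None
            for bid, call in zip(bgc_ids, calls):
                nb = call.neighborhood
                if (
                    nb.record_id == p.orf.record_id
                    and nb.span_start <= p.orf.start
                    and p.orf.end <= nb.span_end
                ):
                    owner = bid
                    break
            if owner is None:
                raise ValueError("precursor ORF not contained in any BGC span")
            precursor_bgc_ids.append(owner)

    class_counts = Counter(c.lan_class for c in calls)
    is_prec = [p for p in precursors if p.is_precursor]
    prec_ids = [bid for bid, p in zip(precursor_bgc_ids, precursors) if p.is_precursor]
    class_by_bgc = dict(zip(bgc_ids, (c.lan_class for c in calls)))
    precursor_class_counts = Counter(class_by_bgc[bid] for bid in prec_ids)

    phylum_counts = Counter()
    gc_pairs: list[tuple[str, float, float]] = []
    for bid, call in zip(bgc_ids, calls):
        rec = by_record.get(call.neighborhood.record_id)
        if rec is None:
            continue
        phylum_counts[_phylum(rec)] += 1
        try:
            pair = (
                gc_content(rec.dna[call.neighborhood.span_start : call.neighborhood.span_end]),
                gc_content(rec.dna),
            )
        except GcError:
            continue
        gc_pairs.append((bid, pair[0], pair[1]))

    gg = sum(1 for p in is_prec if p.boundary.leader.endswith("GG"))
    gg_fraction = gg / len(is_prec) if is_prec else None

    per_bgc = Counter(prec_ids)
    hist = Counter(per_bgc.get(bid, 0) for bid in bgc_ids)

    return MiningReport(
        bgc_calls=list(zip(bgc_ids, calls)),
        precursor_calls=list(zip(precursor_bgc_ids, precursors)),
        class_counts=dict(class_counts),
        precursor_class_counts=dict(precursor_class_counts),
        phylum_counts=dict(phylum_counts),
        gg_leader_fraction=gg_fraction,
        gc_pairs=gc_pairs,
        precursors_per_bgc_hist=dict(hist),
    )
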