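"""Reading annotated genomes, extracting gene neighborhoods, writing outputs.

Internal coordinates are 0-based half-open on the forward strand; GenBank
and GFF3 emit/consume their native 1-based inclusive conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: distance (nt) from a contig end below which a neighborhood is edge-flagged
EDGE_DISTANCE_NT = 3000

TSV_COLUMNS = [
    "record_id",
    "bgc_id",
    "lan_class",
    "anchor_protein_id",
    "orf_start",
    "orf_end",
    "strand",
    "start_codon",
    "annotated",
    "leader_seq",
    "core_seq",
    "rule_used",
    "motif_name",
    "svm_decision",
    "svm_margin",
    "rubric_points",
    "total_score",
    "is_precursor",
]


@dataclass(frozen=True)
class GeneFeature:
    """A single annotated CDS on a replicon."""

    locus_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: int  # +1 / -1
    index: int  # ordinal within record, by start
    protein_id: str | None = None
    product: str = ""
    protein_seq: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gene interval [{self.start}, {self.end})")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")


@dataclass
class GenomeRecord:
    """An annotated replicon: sequence plus ordered gene calls."""

    record_id: str
    dna: str
    genes: list[GeneFeature] = field(default_factory=list)
    organism: str = ""
    lineage: list[str] = field(default_factory=list)
    circular: bool = False

    @property
    def length_nt(self) -> int:
        return len(self.dna)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        for g in self.genes:
            if g.end > self.length_nt:
                raise ValueError(f"gene {g.locus_id} extends past record end")


@dataclass
class Neighborhood:
    """The anchor gene plus up to `window` genes on each side."""

    record_id: str
    anchor: GeneFeature
    genes: list[GeneFeature]
    span_start: int
    span_end: int
    contig_edge: bool
    window: int = 7


def _translate_cds(dna: str, strand: int, table: int = 11) -> str:
    seq = Seq(dna)
    if strand == -1:
        seq = seq.reverse_complement()
    aa = str(seq.translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    # prokaryotic initiator is fMet regardless of codon
    codon = str(seq[:3]).upper()
    if aa and codon in ("ATG", "GTG", "TTG"):
        aa = "M" + aa[1:]
    return aa


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Parse a GenBank flat file into GenomeRecord objects.

    One record per LOCUS. CDS features become GeneFeature entries with
    coordinates converted to 0-based half-open. CDS lacking a translation
    qualifier are translated with genetic code table 11.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        dna = str(rec.seq).upper()
        genes: list[GeneFeature] = []
        cds = [f for f in rec.features if f.type == "CDS"]
        cds.sort(key=lambda f: (int(f.location.start), int(f.location.end)))
        for i, feat in enumerate(cds):
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = 1 if (feat.location.strand or 1) >= 0 else -1
            quals = feat.qualifiers
            locus = quals.get("locus_tag", [f"{rec.id}_cds{i}"])[0]
            protein_id = quals.get("protein_id", [None])[0]
            product = quals.get("product", [""])[0]
            protein = quals.get("translation", [None])[0]
            if protein is None and (end - start) >= 6 and (end - start) % 3 == 0:
                protein = _translate_cds(dna[start:end], strand)
            genes.append(
                GeneFeature(
                    locus_id=locus,
                    protein_id=protein_id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=product,
                    protein_seq=protein,
                    index=i,
                )
            )
        if not genes:
            logger.warning("record %s has no CDS features", rec.id)
        topology = rec.annotations.get("topology", "linear")
        records.append(
            GenomeRecord(
                record_id=rec.id,
                dna=dna,
                genes=genes,
                organism=rec.annotations.get("organism", ""),
                lineage=list(rec.annotations.get("taxonomy", [])),
                circular=(topology == "circular"),
            )
        )
    return records


def write_genbank(records: Sequence[GenomeRecord], path: str | Path) -> None:
    """Write GenomeRecords as a GenBank flat file (inverse of read_genbank)."""
    out = []
    for record in records:
        rec = SeqRecord(Seq(record.dna), id=record.record_id, name=record.record_id[:16], description="")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if record.circular else "linear"
        rec.annotations["organism"] = record.organism
        rec.annotations["source"] = record.organism
        rec.annotations["taxonomy"] = list(record.lineage)
        for g in record.genes:
            quals = {"locus_tag": [g.locus_id]}
            if g.protein_id:
                quals["protein_id"] = [g.protein_id]
            if g.product:
                quals["product"] = [g.product]
            if g.protein_seq:
                quals["translation"] = [g.protein_seq]
            rec.features.append(
                SeqFeature(FeatureLocation(g.start, g.end, strand=g.strand), type="CDS", qualifiers=quals)
            )
        out.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "genbank")


def extract_neighborhood(
    record: GenomeRecord,
    anchor_index: int,
    window: int = 7,
    edge_distance_nt: int = EDGE_DISTANCE_NT,
) -> Neighborhood:
    """Slice the anchor gene and up to `window` genes on each side.

    contig_edge is set when the span lies within `edge_distance_nt` of either
    end of a linear record; circular records are never edge-flagged and the
    window does not wrap the origin.
    """
    if not (0 <= anchor_index < len(record.genes)):
        raise IndexError(f"anchor_index {anchor_index} out of range")
    lo = max(0, anchor_index - window)
    hi = min(len(record.genes), anchor_index + window + 1)
    genes = record.genes[lo:hi]
    span_start = min(g.start for g in genes)
    span_end = max(g.end for g in genes)
    edge = False
    if not record.circular:
        edge = span_start < edge_distance_nt or (record.length_nt - span_end) < edge_distance_nt
    return Neighborhood(
        record_id=record.record_id,
        anchor=record.genes[anchor_index],
        genes=genes,
        span_start=span_start,
        span_end=span_end,
        contig_edge=edge,
        window=window,
    )


def wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{wrap_fasta(seq)}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    entries: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    entries.append((name, "".join(chunks)))
                name = line[1:]
                chunks = []
            elif line:
                chunks.append(line.strip())
    if name is not None:
        entries.append((name, "".join(chunks)))
    return entries


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def precursor_row(bgc_id: str, lan_class: str, anchor_protein_id: str | None, call) -> list[str]:
    """TSV row for one PrecursorCall (column order in TSV_COLUMNS)."""
    orf = call.orf
    b = call.boundary
    return [
        _fmt(orf.record_id),
        _fmt(bgc_id),
        _fmt(lan_class),
        _fmt(anchor_protein_id),
        _fmt(orf.start),
        _fmt(orf.end),
        "+" if orf.strand == 1 else "-",
        _fmt(orf.start_codon),
        _fmt(orf.annotated),
        _fmt(b.leader),
        _fmt(b.core),
        _fmt(b.rule_used),
        _fmt(b.motif_name),
        _fmt(call.svm_decision),
        _fmt(call.svm_margin),
        _fmt(call.rubric_points),
        _fmt(call.total_score),
        _fmt(call.is_precursor),
    ]


def write_report(report, out_dir: str | Path, formats: Iterable[str] = ("tsv", "gff3", "fasta")) -> dict[str, Path]:
    """Write a MiningReport: precursor TSV, GFF3 of ORF coordinates, core FASTA.

    Output is byte-stable across runs for an identical report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    formats = set(formats)
    written: dict[str, Path] = {}
    anchor_by_bgc = {bid: call for bid, call in report.bgc_calls}

    if "tsv" in formats:
        path = out_dir / "precursors.tsv"
        with open(path, "w", newline="") as fh:
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for bgc_id, call in report.precursor_calls:
                bgc = anchor_by_bgc[bgc_id]
                fh.write(
                    "\t".join(precursor_row(bgc_id, bgc.lan_class, bgc.neighborhood.anchor.protein_id, call)) + "\n"
                )
        written["tsv"] = path

    if "gff3" in formats:
        path = out_dir / "precursors.gff3"
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, (bgc_id, call) in enumerate(report.precursor_calls):
                orf = call.orf
                strand = "+" if orf.strand == 1 else "-"
                attrs = f"ID=orf{i};bgc_id={bgc_id};is_precursor={'1' if call.is_precursor else '0'}"
                fh.write(
                    f"{orf.record_id}\tlanminer\tCDS\t{orf.start + 1}\t{orf.end}\t.\t{strand}\t0\t{attrs}\n"
                )
        written["gff3"] = path

    if "fasta" in formats:
        path = out_dir / "cores.fasta"
        entries = []
        for i, (bgc_id, call) in enumerate(report.precursor_calls):
            orf = call.orf
            strand = "+" if orf.strand == 1 else "-"
            entries.append((f"{bgc_id}|orf{i}|{orf.record_id}:{orf.start}-{orf.end}({strand})", call.boundary.core))
        write_fasta(entries, path)
        written["fasta"] = path

    return written


def read_report_tsv(path: str | Path) -> list[dict[str, str]]:
    """Re-parse a precursor TSV into a list of row dicts (round-trip aid)."""
    rows: list[dict[str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows
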