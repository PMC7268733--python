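"""Enumerate and filter candidate precursor ORFs within a neighborhood span.

ORFs run start codon through in-frame stop on either strand. Coordinates are
0-based half-open on the forward strand and include the stop codon, so an
ORF encoding L residues spans 3*(L+1) nt. Codons containing N translate to X
and never act as start or stop codons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from Bio.Data import CodonTable

from lanminer.genome_io import GeneFeature

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE11.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate_codons(dna: str) -> str:
    """Translate complete codons; N-containing or unknown codons give X."""
    aa = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        aa.append(CODON_TO_AA.get(dna[i : i + 3], "X"))
    return "".join(aa)


@dataclass(frozen=True)
class OrfParams:
    start_codons: frozenset[str] = frozenset({"ATG", "GTG", "TTG"})
    min_len_aa: int = 30
    max_len_aa: int = 120
    require_cys: bool = True
    genetic_code: int = 11

    def __post_init__(self) -> None:
        if self.min_len_aa > self.max_len_aa:
            raise ValueError("min_len_aa > max_len_aa")


@dataclass(frozen=True)
class CandidateOrf:
    """An enumerated short ORF, including its stop codon in [start, end)."""

    record_id: str
    start: int
    end: int
    strand: int
    start_codon: str
    aa_seq: str  # begins with M; stop symbol excluded
    stop_key: tuple[int, int]  # (strand, forward coord of stop codon's first nt)
    annotated: bool = False

    def __post_init__(self) -> None:
        if len(self.aa_seq) != (self.end - self.start) // 3 - 1:
            raise ValueError("aa_seq length inconsistent with coordinates")


def _scan_strand(dna: str, strand: int, span_len: int, offset: int, record_id: str, params: OrfParams):
    """Yield ORFs on one strand; `dna` is already in reading orientation."""
    n = len(dna)
    for frame in range(3):
        pending_starts: list[int] = []  # codon start positions awaiting a stop
        for i in range(frame, n - 2, 3):
            codon = dna[i : i + 3]
            if codon in STOP_CODONS:
                for s in pending_starts:
                    aa = translate_codons(dna[s:i])
                    aa = "M" + aa[1:]
                    if strand == 1:
                        start, end = offset + s, offset + i + 3
                        stop_nt = offset + i
                    else:
                        # map reading-orientation coords back to forward strand
                        start = offset + (span_len - (i + 3))
                        end = offset + (span_len - s)
                        stop_nt = start
                    yield CandidateOrf(
                        record_id=record_id,
                        start=start,
                        end=end,
                        strand=strand,
                        start_codon=dna[s : s + 3],
                        aa_seq=aa,
                        stop_key=(strand, stop_nt),
                    )
                pending_starts = []
            elif codon in params.start_codons:
                pending_starts.append(i)


def enumerate_orfs(
    span_dna: str,
    span_offset: int = 0,
    params: OrfParams = OrfParams(),
    record_id: str = "",
) -> list[CandidateOrf]:
    """All (start codon ... in-frame stop) ORFs on both strands of a span.

    One CandidateOrf per start codon; the initiator translates as M
    regardless of codon. ORFs that run off the span without a stop are
    excluded. Coordinates are reported in record space via `span_offset`.
    """
    span_dna = span_dna.upper()
    orfs = list(_scan_strand(span_dna, 1, len(span_dna), span_offset, record_id, params))
    orfs += list(_scan_strand(revcomp(span_dna), -1, len(span_dna), span_offset, record_id, params))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def _contained(orf: CandidateOrf, gene: GeneFeature) -> bool:
    return gene.start <= orf.start and orf.end <= gene.end


def filter_orfs(
    orfs: Sequence[CandidateOrf],
    genes: Sequence[GeneFeature],
    params: OrfParams = OrfParams(),
) -> list[CandidateOrf]:
    """Apply the precursor candidacy filters.

    Keeps ORFs whose peptide length is within [min_len_aa, max_len_aa]
    (inclusive, initiator Met counted), that encode at least one Cys, and
    that are not contained within an annotated gene — except an ORF whose
    interval exactly equals an annotated gene's, which is kept and marked
    annotated.
    """
    kept: list[CandidateOrf] = []
    for orf in orfs:
        L = len(orf.aa_seq)
        if L < params.min_len_aa or L > params.max_len_aa:
            continue
        if params.require_cys and "C" not in orf.aa_seq:
            continue
        coincident = any(g.start == orf.start and g.end == orf.end for g in genes)
        if not coincident and any(_contained(orf, g) for g in genes):
            continue
        kept.append(replace(orf, annotated=coincident) if coincident != orf.annotated else orf)
    return kept


def dedup_by_stop(orfs: Sequence[CandidateOrf]) -> list[CandidateOrf]:
    """Keep the longest ORF per stop codon (the most upstream start)."""
    best: dict[tuple[int, int], CandidateOrf] = {}
    for orf in orfs:
        cur = best.get(orf.stop_key)
        if cur is None or len(orf.aa_seq) > len(cur.aa_seq):
            best[orf.stop_key] = orf
    out = list(best.values())
    out.sort(key=lambda o: (o.start, o.strand))
    return out
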