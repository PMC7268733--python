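"""Deterministic synthetic genomes, peptide sets, and alignment families.

Every planted element is emitted from the same column profiles the fixture
HMMs are built from, so anchor/class detection works without any external
model files. Planted ORFs are reverse-translated without internal in-frame
start codons and with an in-frame stop immediately upstream, so their
coordinates survive enumeration and stop-codon deduplication exactly.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from lanminer.genome_io import GeneFeature, GenomeRecord
from lanminer.hmm_profiles import Alignment, ProfileHmm, build_hmm
from lanminer.orf_extract import enumerate_orfs, revcomp

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: residues used for random peptide positions (no Met: ATG is the only Met
#: codon and would create internal in-frame starts)
BACKGROUND = "ACDEFGHIKLNPQRSTVWY"
#: leader positions avoid G/S/T/C so no cleavage candidate precedes the
#: planted one
LEADER_BG = "ADEFHIKLNPQRVWY"

# codons per residue, ATG/GTG/TTG excluded so planted ORFs have no internal
# in-frame start codons
_SAFE_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_ALL_CODONS = {aa: list(codons) for aa, codons in _SAFE_CODONS.items()}
_ALL_CODONS["V"] = _ALL_CODONS["V"] + ["GTG"]
_ALL_CODONS["L"] = _ALL_CODONS["L"] + ["TTG"]

ROLE_SEEDS = {
    "anchor": 101,
    "class1_n": 102,
    "class1_c": 103,
    "class2": 104,
    "kinase": 105,
    "tailor": 106,
}
ROLE_LENGTHS = {
    "anchor": 120,
    "class1_n": 130,
    "class1_c": 100,
    "class2": 140,
    "kinase": 110,
    "tailor": 100,
}
#: fraction of anchor-profile columns replaced in the class III / IV
#: cyclase subfamily profiles
SUBFAMILY_MUTATION = 0.3
DEFAULT_DIVERGENCE = 0.08


# ---------------------------------------------------------------------------
# family profiles and alignments


def _random_profile(length: int, rng: random.Random) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))


def role_profile(role: str) -> str:
    """Deterministic dominant-residue profile for a fixture domain role."""
    if role in ("class3", "class4"):
        base = role_profile("anchor")
        rng = random.Random(200 if role == "class3" else 201)
        cols = list(base)
        for i in range(len(cols)):
            if rng.random() < SUBFAMILY_MUTATION:
                cols[i] = rng.choice(AA20.replace(cols[i], ""))
        return "".join(cols)
    rng = random.Random(ROLE_SEEDS[role])
    return _random_profile(ROLE_LENGTHS[role], rng)


def sample_from_profile(profile: str, rng: random.Random, divergence: float = DEFAULT_DIVERGENCE) -> str:
    return "".join(
        rng.choice(AA20) if rng.random() < divergence else c for c in profile
    )


def sample_role_protein(role: str, rng: random.Random, divergence: float = DEFAULT_DIVERGENCE) -> str:
    return sample_from_profile(role_profile(role), rng, divergence)


def make_alignment_family(
    n_rows: int, length: int, divergence: float, seed: int, aln_id: str | None = None
) -> Alignment:
    """Rows sampled from one random column profile at the given per-column
    substitution rate; gap-free and deterministic per seed."""
    if n_rows < 2:
        raise ValueError("need at least 2 rows")
    rng = random.Random(seed)
    profile = _random_profile(length, rng)
    rows = tuple(
        (f"seq{i}", sample_from_profile(profile, rng, divergence)) for i in range(n_rows)
    )
    return Alignment(id=aln_id or f"family_s{seed}", rows=rows)


def role_alignment(role: str, n_rows: int = 20, divergence: float = DEFAULT_DIVERGENCE, seed: int = 7) -> Alignment:
    import zlib

    rng = random.Random(zlib.crc32(role.encode()) ^ (seed * 2654435761 & 0x7FFFFFFF))
    profile = role_profile(role)
    rows = tuple(
        (f"{role}{i}", sample_from_profile(profile, rng, divergence)) for i in range(n_rows)
    )
    return Alignment(id=f"{role}_family", rows=rows)


def build_role_hmms(out_dir: str | Path, roles: Sequence[str] = ("anchor", "class1_n", "class1_c", "class2", "kinase", "class3", "class4")) -> dict[str, ProfileHmm]:
    """Build one fixture HMM per role under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_seed = 7
    models = {}
    for role in roles:
        aln = role_alignment(role, seed=rng_seed)
        models[role] = build_hmm(aln, name=f"fx_{role}", out_path=out_dir / f"{role}.hmm")
    return models


# ---------------------------------------------------------------------------
# peptides


def _reverse_translate(aa: str, rng: random.Random, safe: bool = True) -> str:
    table = _SAFE_CODONS if safe else _ALL_CODONS
    return "".join(rng.choice(table[a]) for a in aa)


@dataclass(frozen=True)
class PlantedPeptide:
    aa_seq: str
    boundary: int  # ground-truth core start
    motif_name: str | None
    cleavage_rule: str  # GG | GA | STC | fallback-half


_MOTIF_BUILDERS = {
    "FxLD": lambda rng: "F" + rng.choice(LEADER_BG) + "LD",
    "LxLxKx5L": lambda rng: "L" + rng.choice(LEADER_BG) + "L" + rng.choice(LEADER_BG) + "K"
    + "".join(rng.choice(LEADER_BG) for _ in range(5)) + "L",
    "LxLQ": lambda rng: "L" + rng.choice(LEADER_BG) + "LQ",
    "ED-LM": lambda rng: rng.choice("ED") + rng.choice("LM"),
}


def make_precursor_peptide(
    rng: random.Random,
    motif: str = "FxLD",
    cleavage: str = "GG",
    core_stc_fraction: float = 0.55,
    leader_len: int | None = None,
    core_len: int | None = None,
) -> PlantedPeptide:
    """A peptide whose leader motif, cleavage site, and S/T/C-rich core are
    all known ground truth recoverable by the boundary heuristic."""
    leader_len = leader_len if leader_len is not None else rng.randint(18, 26)
    core_len = core_len if core_len is not None else rng.randint(16, 28)
    motif_seq = _MOTIF_BUILDERS[motif](rng) if motif and motif != "none" else ""
    motif_pos = rng.randint(2, 5)

    def bg(n: str | int) -> str:
        return "".join(rng.choice(LEADER_BG) for _ in range(int(n)))

    if cleavage in ("GG", "GA"):
        pre = bg(leader_len - motif_pos - len(motif_seq) - 2)
        leader = "M" + bg(motif_pos - 1) + motif_seq + pre + cleavage
        # first core residue must not be S/T, else an S/T(x)2-7C occurrence
        # one position earlier would outrank the planted cleavage site
        core = rng.choice(LEADER_BG) + _rich_core(rng, core_len - 1, core_stc_fraction)
        rule = cleavage
    elif cleavage == "STC":
        # core starts 1 residue before the S/T; C within the 2-7 spacer
        pre = bg(leader_len - motif_pos - len(motif_seq) - 1)
        leader = "M" + bg(motif_pos - 1) + motif_seq + pre
        spacer = rng.randint(2, 7)
        head = rng.choice(LEADER_BG) + rng.choice("ST") + bg(spacer) + "C"
        core = head + _rich_core(rng, max(core_len - len(head), 9), core_stc_fraction)
        rule = "STC"
    else:  # fallback-half: no qualifying occurrence anywhere
        body_len = leader_len + core_len
        body = "M" + bg(motif_pos - 1) + motif_seq + bg(body_len - motif_pos - len(motif_seq) - 9)
        # S/T/C confined to the last 9 residues (ignored region) keeps the
        # fallback rule in force while still providing a core Cys
        tail = "C" + "".join(rng.choice("STC" + LEADER_BG) for _ in range(8))
        peptide = body + tail
        return PlantedPeptide(
            aa_seq=peptide,
            boundary=len(peptide) // 2,
            motif_name=motif if motif and motif != "none" else None,
            cleavage_rule="fallback-half",
        )
    peptide = leader + core
    return PlantedPeptide(
        aa_seq=peptide,
        boundary=len(leader),
        motif_name=motif if motif and motif != "none" else None,
        cleavage_rule=rule,
    )


def _rich_core(rng: random.Random, n: int, stc_fraction: float) -> str:
    core = [
        rng.choice("STC") if rng.random() < stc_fraction else rng.choice(LEADER_BG)
        for _ in range(n)
    ]
    if "C" not in core:
        core[rng.randrange(n)] = "C"
    return "".join(core)


def _random_peptide(rng: random.Random, length: int) -> str:
    return "M" + "".join(rng.choice(BACKGROUND) for _ in range(length - 1))


def make_training_peptides(
    n_pos: int, n_neg: int, separation: float, seed: int
) -> list[tuple[str, str, int]]:
    """Labeled (id, peptide, label) training set.

    Positives carry a leader motif, GG cleavage, and S/T/C-enriched cores
    with intensity scaled by `separation`; negatives are composition-matched
    random peptides. At separation 0 both labels are drawn from the same
    process, so no classifier can beat chance.
    """
    if n_pos < 10 or n_neg < 10:
        raise ValueError("need at least 10 peptides per label")
    rng = random.Random(seed)
    out: list[tuple[str, str, int]] = []
    stc = min(0.08 + 0.12 * separation, 0.85)
    for i in range(n_pos):
        if separation <= 0:
            pep = _random_peptide(rng, rng.randint(36, 56))
        else:
            pep = make_precursor_peptide(rng, motif="FxLD", cleavage="GG", core_stc_fraction=stc).aa_seq
        out.append((f"pos{i}", pep, 1))
    for i in range(n_neg):
        pep = _random_peptide(rng, rng.randint(36, 56))
        out.append((f"neg{i}", pep, 0))
    return out


def write_labeled_fasta(peptides: Sequence[tuple[str, str, int]], path: str | Path) -> None:
    from lanminer.genome_io import write_fasta

    write_fasta([(f"{pid} label={label}", seq) for pid, seq, label in peptides], path)


def read_labeled_fasta(path: str | Path) -> list[tuple[str, str, int]]:
    from lanminer.genome_io import read_fasta

    out = []
    for name, seq in read_fasta(path):
        fields = name.split()
        label = None
        for f in fields[1:]:
            if f.startswith("label="):
                label = int(f.split("=", 1)[1])
        if label is None:
            raise ValueError(f"entry {fields[0]} lacks a label=0|1 key")
        out.append((fields[0], seq, label))
    return out


# ---------------------------------------------------------------------------
# genomes


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    classes: tuple[str, ...] = ("I", "II", "III")
    intergenic_gc: float = 0.5
    precursors_per_bgc: int = 1
    decoys_per_bgc: int = 2
    decoy_rules: tuple[str, ...] = ("too_short", "too_long", "no_cys", "nested")
    leader_motif: str = "FxLD"
    cleavage: str = "GG"
    core_stc_fraction: float = 0.55
    contig_edge_case: bool = False
    lineage: tuple[str, ...] = ("Bacteria", "Firmicutes", "Bacillales")

    def __post_init__(self) -> None:
        if not 0 < self.intergenic_gc < 1:
            raise ValueError("intergenic_gc must be in (0, 1)")
        if self.precursors_per_bgc < 0:
            raise ValueError("precursors_per_bgc must be >= 0")
        for c in self.classes:
            if c not in ("I", "II", "III", "IV"):
                raise ValueError(f"unknown class {c}")

    @property
    def n_bgcs(self) -> int:
        return len(self.classes)


@dataclass
class PlantedOrf:
    start: int
    end: int  # includes the stop codon
    strand: int
    aa_seq: str
    kind: str  # "precursor" | "decoy"
    violates: str | None = None  # decoy rule: too_short | too_long | no_cys | nested | none
    boundary: int | None = None
    motif_name: str | None = None
    cleavage_rule: str | None = None


@dataclass
class PlantedBgc:
    lan_class: str
    anchor_locus: str
    anchor_protein_id: str
    anchor_gene_index: int
    gene_indices: list[int]
    precursors: list[PlantedOrf]
    decoys: list[PlantedOrf]


@dataclass
class GroundTruth:
    record_id: str
    bgcs: list[PlantedBgc]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


class _Builder:
    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        self.rng = random.Random(spec.seed)
        self.parts: list[str] = []
        self.cursor = 0
        self.genes: list[GeneFeature] = []
        self._counter = 0

    def _emit(self, dna: str) -> int:
        start = self.cursor
        self.parts.append(dna)
        self.cursor += len(dna)
        return start

    def intergenic(self, n: int) -> None:
        gc = self.spec.intergenic_gc
        bases = "".join(
            self.rng.choice("GC") if self.rng.random() < gc else self.rng.choice("AT")
            for _ in range(n)
        )
        self._emit(bases)

    def gene(self, aa: str, product: str, strand: int = 1, dna: str | None = None) -> int:
        """Add an annotated CDS; returns its index. `dna` overrides coding DNA."""
        if dna is None:
            dna = "ATG" + _reverse_translate(aa[1:], self.rng, safe=False) + "TAA"
        if strand == -1:
            dna = revcomp(dna)
        start = self._emit(dna)
        self._counter += 1
        idx = len(self.genes)
        self.genes.append(
            GeneFeature(
                locus_id=f"L{self._counter:04d}",
                protein_id=f"P{self._counter:04d}",
                start=start,
                end=start + len(dna),
                strand=strand,
                product=product,
                protein_seq=aa,
                index=idx,
            )
        )
        return idx

    def planted_orf(self, aa: str, strand: int = 1) -> tuple[int, int]:
        """Unannotated ORF with an in-frame upstream stop blocker; returns
        its (start, end) with end including the stop codon."""
        dna = "TAA" + "ATG" + _reverse_translate(aa[1:], self.rng, safe=True) + "TAA"
        if strand == -1:
            blocked = revcomp(dna)
            start0 = self._emit(blocked)
            return start0, start0 + len(blocked) - 3
        start0 = self._emit(dna)
        return start0 + 3, start0 + len(dna)


def _random_protein(rng: random.Random, n: int) -> str:
    return "M" + "".join(rng.choice(AA20) for _ in range(n - 1))


def _filler_with_nested_orf(rng: random.Random) -> tuple[str, str, tuple[int, int, int, str]]:
    """A filler protein whose coding DNA contains, in another frame, an ORF
    of 30-120 aa with a Cys. Found by seeded rejection sampling; returns the
    exact coding DNA so the planted coordinates stay valid."""
    for _ in range(500):
        aa = _random_protein(rng, 300)
        dna = "ATG" + _reverse_translate(aa[1:], rng, safe=False) + "TAA"
        for orf in enumerate_orfs(dna):
            ln = len(orf.aa_seq)
            if 30 <= ln <= 120 and "C" in orf.aa_seq and (orf.start, orf.end) != (0, len(dna)):
                return aa, dna, (orf.start, orf.end, orf.strand, orf.aa_seq)
    raise RuntimeError("could not synthesize a nested-ORF filler gene")


def make_genome(spec: FixtureSpec) -> tuple[GenomeRecord, GroundTruth]:
    """Deterministic genome with one planted BGC per entry in spec.classes.

    Each BGC carries a recognizable anchor gene, class-defining genes,
    `precursors_per_bgc` planted precursor ORFs (leader motif + cleavage +
    S/T/C-rich core), `decoys_per_bgc` filter-passing decoy ORFs, and one
    decoy per rule in `decoy_rules`, each violating exactly that rule.
    """
    b = _Builder(spec)
    rng = b.rng
    truth_bgcs: list[PlantedBgc] = []

    b.intergenic(600 if spec.contig_edge_case else 3600)

    for bgc_i, lan_class in enumerate(spec.classes):
        gene_indices: list[int] = []
        precursors: list[PlantedOrf] = []
        decoys: list[PlantedOrf] = []

        gene_indices.append(b.gene(_random_protein(rng, 180), "hypothetical protein"))
        b.intergenic(rng.randint(60, 140))

        if lan_class == "I":
            gene_indices.append(b.gene(sample_role_protein("class1_n", rng), "dehydratase N"))
            b.intergenic(rng.randint(40, 90))
            gene_indices.append(b.gene(sample_role_protein("class1_c", rng), "dehydratase C"))
            anchor_aa = sample_role_protein("anchor", rng)
        elif lan_class == "II":
            anchor_aa = sample_role_protein("class2", rng) + sample_role_protein("anchor", rng)
        elif lan_class == "III":
            anchor_aa = sample_role_protein("kinase", rng) + sample_role_protein("class3", rng)
        else:
            anchor_aa = sample_role_protein("kinase", rng) + sample_role_protein("class4", rng)

        # precursor/decoy ORFs sit between the class genes and the anchor so
        # they are adjacent and co-directional with the class-defining gene
        b.intergenic(rng.randint(40, 90))
        for _ in range(spec.precursors_per_bgc):
            planted = make_precursor_peptide(
                rng,
                motif=spec.leader_motif,
                cleavage=spec.cleavage,
                core_stc_fraction=spec.core_stc_fraction,
            )
            start, end = b.planted_orf(planted.aa_seq)
            precursors.append(
                PlantedOrf(
                    start=start,
                    end=end,
                    strand=1,
                    aa_seq=planted.aa_seq,
                    kind="precursor",
                    boundary=planted.boundary,
                    motif_name=planted.motif_name,
                    cleavage_rule=planted.cleavage_rule,
                )
            )
            b.intergenic(rng.randint(25, 50))

        for _ in range(spec.decoys_per_bgc):
            aa = _random_peptide(rng, rng.randint(40, 80))
            if "C" not in aa:
                aa = aa[:-1] + "C"
            start, end = b.planted_orf(aa)
            decoys.append(PlantedOrf(start=start, end=end, strand=1, aa_seq=aa, kind="decoy", violates="none"))
            b.intergenic(rng.randint(25, 50))

        for rule in spec.decoy_rules:
            if rule == "nested":
                continue  # handled via the trailing filler gene below
            if rule == "too_short":
                aa = _random_peptide(rng, 20)
                aa = aa[:-1] + "C"
            elif rule == "too_long":
                aa = _random_peptide(rng, 130)
                aa = aa[:-1] + "C"
            elif rule == "no_cys":
                aa = "M" + "".join(rng.choice(BACKGROUND.replace("C", "")) for _ in range(59))
            else:
                raise ValueError(f"unknown decoy rule {rule}")
            start, end = b.planted_orf(aa)
            decoys.append(PlantedOrf(start=start, end=end, strand=1, aa_seq=aa, kind="decoy", violates=rule))
            b.intergenic(rng.randint(25, 50))

        anchor_idx = b.gene(anchor_aa, "lanthipeptide synthetase")
        gene_indices.append(anchor_idx)
        b.intergenic(rng.randint(60, 140))

        if "nested" in spec.decoy_rules:
            filler_aa, dna, nested = _filler_with_nested_orf(rng)
            gstart = b.cursor
            gi = b.gene(filler_aa, "hypothetical protein", dna=dna)
            gene_indices.append(gi)
            ns, ne, nstrand, naa = nested
            decoys.append(
                PlantedOrf(
                    start=gstart + ns,
                    end=gstart + ne,
                    strand=nstrand,
                    aa_seq=naa,
                    kind="decoy",
                    violates="nested",
                )
            )
        else:
            gene_indices.append(b.gene(_random_protein(rng, 200), "hypothetical protein"))

        anchor_gene = b.genes[anchor_idx]
        truth_bgcs.append(
            PlantedBgc(
                lan_class=lan_class,
                anchor_locus=anchor_gene.locus_id,
                anchor_protein_id=anchor_gene.protein_id,
                anchor_gene_index=anchor_idx,
                gene_indices=gene_indices,
                precursors=precursors,
                decoys=decoys,
            )
        )
        b.intergenic(rng.randint(300, 500))
        # insulator genes keep a 7-gene window from reaching the next BGC
        for _ in range(7):
            b.gene(_random_protein(rng, rng.randint(150, 250)), "hypothetical protein")
            b.intergenic(rng.randint(40, 90))
        b.intergenic(rng.randint(300, 500))

    b.intergenic(3600)
    record = GenomeRecord(
        record_id=f"FIXTURE_{spec.seed}",
        dna="".join(b.parts),
        genes=b.genes,
        organism="Synthetica planta",
        lineage=list(spec.lineage),
        circular=False,
    )
    return record, GroundTruth(record_id=record.record_id, bgcs=truth_bgcs)
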