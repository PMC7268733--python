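"""Independent brute-force oracles, deliberately written without reusing any
implementation internals they are meant to check."""

from __future__ import annotations

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# minimal table-11 translation for the oracle, spelled out independently
_ORACLE_CODONS = {}
for _aas, _bases in [
    ("F", ("TTT", "TTC")), ("L", ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG")),
    ("I", ("ATT", "ATC", "ATA")), ("M", ("ATG",)),
    ("V", ("GTT", "GTC", "GTA", "GTG")), ("S", ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC")),
    ("P", ("CCT", "CCC", "CCA", "CCG")), ("T", ("ACT", "ACC", "ACA", "ACG")),
    ("A", ("GCT", "GCC", "GCA", "GCG")), ("Y", ("TAT", "TAC")),
    ("H", ("CAT", "CAC")), ("Q", ("CAA", "CAG")), ("N", ("AAT", "AAC")),
    ("K", ("AAA", "AAG")), ("D", ("GAT", "GAC")), ("E", ("GAA", "GAG")),
    ("C", ("TGT", "TGC")), ("W", ("TGG",)),
    ("R", ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG")),
    ("G", ("GGT", "GGC", "GGA", "GGG")),
]:
    for _b in _bases:
        _ORACLE_CODONS[_b] = _aas
ORACLE_STOPS = {"TAA", "TAG", "TGA"}
ORACLE_STARTS = {"ATG", "GTG", "TTG"}


def oracle_revcomp(dna: str) -> str:
    return "".join(COMP[b] for b in reversed(dna))


def brute_force_orfs(dna: str, offset: int = 0) -> set[tuple[int, int, int, str]]:
    """Every (start, end, strand, peptide) ORF, by walking forward from each
    start codon position until the first in-frame stop. `end` includes the
    stop codon; coordinates are forward-strand, shifted by `offset`."""
    found: set[tuple[int, int, int, str]] = set()
    n = len(dna)
    for strand in (1, -1):
        seq = dna if strand == 1 else oracle_revcomp(dna)
        for i in range(n - 2):
            if seq[i : i + 3] not in ORACLE_STARTS:
                continue
            j = i + 3
            while j + 3 <= n:
                codon = seq[j : j + 3]
                if codon in ORACLE_STOPS:
                    pep = "M" + "".join(
                        _ORACLE_CODONS.get(seq[k : k + 3], "X") for k in range(i + 3, j, 3)
                    )
                    if strand == 1:
                        found.add((offset + i, offset + j + 3, 1, pep))
                    else:
                        found.add((offset + n - (j + 3), offset + n - i, -1, pep))
                    break
                j += 3
    return found


def oracle_split(peptide: str, search_start: int = 0):
    """Exhaustive enumeration of boundary candidates; returns
    (boundary, rule) or None when the core would lack Cys."""
    L = len(peptide)
    candidates: list[tuple[int, int]] = []  # (boundary, rule_priority)
    rules = {}
    for i in range(L - 1):
        if i < search_start or i >= L - 10:
            continue
        if peptide[i : i + 2] == "GG":
            candidates.append((i + 2, 0))
        elif peptide[i : i + 2] == "GA":
            candidates.append((i + 2, 1))
    for k in range(L):
        if k < search_start or k < 2 or k >= L - 10:
            continue
        if peptide[k] in "ST" and any(
            k + 1 + s < L and peptide[k + 1 + s] == "C" for s in range(2, 8)
        ):
            candidates.append((k - 1, 2))
    if candidates:
        boundary, prio = min(candidates)
        rule = {0: "GG", 1: "GA", 2: "STC"}[prio]
    else:
        boundary, rule = L // 2, "fallback-half"
    if "C" not in peptide[boundary:]:
        return None
    return boundary, rule


def oracle_anova_p(groups) -> float:
    """Closed-form one-way ANOVA p-value, F = MSbetween / MSwithin."""
    from scipy.stats import f as fdist

    k = len(groups)
    ns = [len(g) for g in groups]
    n = sum(ns)
    grand = sum(sum(g) for g in groups) / n
    ssb = sum(m * (sum(g) / m - grand) ** 2 for g, m in zip(groups, ns))
    ssw = sum(sum((x - sum(g) / m) ** 2 for x in g) for g, m in zip(groups, ns))
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    F = msb / msw
    return float(fdist.sf(F, k - 1, n - k))
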