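"""Profile-HMM construction and search behind a backend-agnostic contract.

Backed by the HMMER3 command-line tools (hmmbuild / hmmsearch). Only
full-sequence E-values and bit scores are consumed downstream; searches use
a fixed effective database size so that E-values are comparable across runs
regardless of how many query proteins are in the batch.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
GAP = "-"

#: fixed effective database size passed to hmmsearch (-Z)
SEARCH_Z = 1_000_000
#: hmmsearch default per-target reporting threshold, used when no cutoff given
DEFAULT_REPORT_E = 10.0
_BUILD_SEED = 42


class HmmBackendError(RuntimeError):
    """The external HMMER tool failed or is unavailable."""


@dataclass(frozen=True)
class ProfileHmm:
    """A searchable profile HMM (file on disk, HMMER3 text format)."""

    name: str
    path: Path
    model_length: int
    provenance: str  # "external-file" | "built-from-alignment"
    source: str
    accession: str | None = None

    def __post_init__(self) -> None:
        if self.model_length < 1:
            raise ValueError("model_length must be >= 1")


@dataclass(frozen=True)
class Alignment:
    """A multiple protein alignment; rows are (id, aligned sequence)."""

    id: str
    rows: tuple[tuple[str, str], ...]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        n = len(self.rows[0][1])
        if any(len(seq) != n for _, seq in self.rows):
            raise ValueError("ragged alignment")


@dataclass(frozen=True)
class HmmHit:
    """One (protein, model) match; E-value is full-sequence."""

    protein_id: str
    hmm_name: str
    evalue: float
    bitscore: float
    env_start: int | None = None
    env_end: int | None = None

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")


def _require(tool: str) -> str:
    exe = shutil.which(tool)
    if exe is None:
        raise HmmBackendError(f"required backend tool not on PATH: {tool}")
    return exe


def truncate_alignment(aln: Alignment, first_col: int, last_col: int) -> Alignment:
    """Column slice [first_col, last_col], 1-based inclusive.

    Rows that become all-gap are dropped; order is preserved.
    """
    if not (1 <= first_col <= last_col <= aln.n_columns):
        raise ValueError(f"bad column slice {first_col}..{last_col} for {aln.n_columns} columns")
    rows = []
    for name, seq in aln.rows:
        piece = seq[first_col - 1 : last_col]
        if set(piece) != {GAP}:
            rows.append((name, piece))
    if len(rows) < 2:
        raise ValueError("slice leaves fewer than 2 non-gap rows; cannot build an HMM")
    return Alignment(id=f"{aln.id}/{first_col}-{last_col}", rows=tuple(rows))


def write_stockholm(aln: Alignment, path: str | Path) -> None:
    width = max(len(name) for name, _ in aln.rows) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for name, seq in aln.rows:
            fh.write(f"{name:<{width}}{seq.replace(GAP, '.')}\n")
        fh.write("//\n")


def read_alignment_fasta(path: str | Path, aln_id: str | None = None) -> Alignment:
    from lanminer.genome_io import read_fasta

    rows = tuple((name.split()[0], seq.upper()) for name, seq in read_fasta(path))
    return Alignment(id=aln_id or Path(path).stem, rows=rows)


def _normalize_hmm_file(path: Path) -> None:
    # hmmbuild stamps a DATE line; fix it so identical inputs give identical bytes
    text = path.read_text()
    text = re.sub(r"^DATE .*$", "DATE  (normalized)", text, flags=re.MULTILINE)
    path.write_text(text)


def _parse_model_length(path: Path) -> int:
    for line in path.read_text().splitlines():
        if line.startswith("LENG"):
            return int(line.split()[1])
    raise HmmBackendError(f"no LENG line in HMM file {path}")


def build_hmm(aln: Alignment, name: str, out_path: str | Path | None = None) -> ProfileHmm:
    """Build a profile HMM from an alignment with hmmbuild.

    Deterministic for a fixed alignment and backend version (fixed RNG seed,
    normalized DATE stamp).
    """
    if all(set(seq) <= {GAP} for _, seq in aln.rows):
        raise ValueError("degenerate alignment: all gaps")
    hmmbuild = _require("hmmbuild")
    if out_path is None:
        out_path = Path(tempfile.mkdtemp(prefix="lanminer_hmm_")) / f"{name}.hmm"
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with tempfile.TemporaryDirectory() as tmp:
        sto = Path(tmp) / "aln.sto"
        write_stockholm(aln, sto)
        proc = subprocess.run(
            [hmmbuild, "--amino", "--seed", str(_BUILD_SEED), "-n", name, str(out_path), str(sto)],
            capture_output=True,
            text=True,
        )
    if proc.returncode != 0:
        raise HmmBackendError(f"hmmbuild failed: {proc.stderr.strip()}")
    _normalize_hmm_file(out_path)
    return ProfileHmm(
        name=name,
        path=out_path,
        model_length=_parse_model_length(out_path),
        provenance="built-from-alignment",
        source=aln.id,
    )


def load_hmm(path: str | Path, name: str | None = None) -> ProfileHmm:
    """Wrap an existing HMMER3 text-format model file."""
    path = Path(path)
    accession = None
    model_name = None
    for line in path.read_text().splitlines():
        if line.startswith("NAME"):
            model_name = line.split()[1]
        elif line.startswith("ACC"):
            accession = line.split()[1]
        elif line.startswith("LENG"):
            break
    return ProfileHmm(
        name=name or model_name or path.stem,
        path=path,
        model_length=_parse_model_length(path),
        provenance="external-file",
        source=str(path),
        accession=accession,
    )


def _clean_proteins(proteins: Iterable[tuple[str, str]]) -> list[tuple[str, str]]:
    kept = []
    for pid, seq in proteins:
        seq = seq.upper()
        if not seq or not set(seq) <= AA_ALPHABET:
            bad = sorted(set(seq) - AA_ALPHABET)
            logger.warning("skipping protein %s: invalid characters %s", pid, bad)
            continue
        kept.append((pid, seq))
    return kept


def hmm_search(
    hmms: Sequence[ProfileHmm],
    proteins: Sequence[tuple[str, str]],
    e_cutoff: float | None = None,
) -> list[HmmHit]:
    """Search proteins with one or more profile HMMs.

    Returns every (protein, model) pair whose full-sequence E-value is at or
    below `e_cutoff` (backend default reporting threshold when None), sorted
    by ascending E-value. E-values use a fixed effective database size.
    """
    if not hmms:
        raise ValueError("need at least one HMM")
    proteins = _clean_proteins(proteins)
    if not proteins:
        return []
    hmmsearch = _require("hmmsearch")
    hits: list[HmmHit] = []
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        db = tmp / "db.fasta"
        from lanminer.genome_io import write_fasta

        write_fasta(proteins, db)
        hmmfile = tmp / "models.hmm"
        with open(hmmfile, "w") as out:
            for hmm in hmms:
                out.write(Path(hmm.path).read_text())
        tbl = tmp / "hits.tbl"
        cmd = [
            hmmsearch,
            "--tblout",
            str(tbl),
            "-Z",
            str(SEARCH_Z),
            "-E",
            str(e_cutoff if e_cutoff is not None else DEFAULT_REPORT_E),
            str(hmmfile),
            str(db),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise HmmBackendError(f"hmmsearch failed: {proc.stderr.strip()}")
        for line in tbl.read_text().splitlines():
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            target, query, evalue, score = parts[0], parts[2], float(parts[4]), float(parts[5])
            hits.append(HmmHit(protein_id=target, hmm_name=query, evalue=evalue, bitscore=score))
    if e_cutoff is not None:
        hits = [h for h in hits if h.evalue <= e_cutoff]
    hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.protein_id, h.hmm_name))
    return hits
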