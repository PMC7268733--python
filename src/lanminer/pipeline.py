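"""End-to-end mining and training runs.

run_mine executes: read -> anchor search -> neighborhoods -> classify ->
ORF enumerate/filter/dedup -> precursor calling -> annotation -> summary.
The stage-count funnel (candidates >= filtered >= deduplicated >= called
precursors) is logged and recorded on the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from lanminer import genome_io
from lanminer.bgc_classify import BgcCall, ClassifierConfig, assign_class, find_lanc_proteins
from lanminer.cluster_annotate import annotate_genes, census, summarize
from lanminer.genome_io import GenomeRecord, extract_neighborhood, read_genbank
from lanminer.hmm_profiles import ProfileHmm, hmm_search, load_hmm
from lanminer.orf_extract import OrfParams, dedup_by_stop, enumerate_orfs, filter_orfs
from lanminer.precursor_score import (
    BoundaryParams,
    FeatureCatalog,
    MotifLibrary,
    ScoreRubric,
    SvmModel,
    TrainingConfig,
    call_precursors,
    prepare_training_matrix,
    select_features,
    train_svm,
)
from lanminer.report import MiningReport

logger = logging.getLogger(__name__)


class ConfigError(RuntimeError):
    """Configuration is invalid or references missing files."""


class InputError(RuntimeError):
    """No input record could be parsed."""


@dataclass
class PipelineConfig:
    classifier: ClassifierConfig
    models: Mapping[str, SvmModel] = field(default_factory=dict)  # per lan_class
    annotation_models: Sequence[ProfileHmm] = ()
    annotation_e_cutoff: float = 1e-5
    window: int = 7
    edge_distance_nt: int = 3000
    orf: OrfParams = OrfParams()
    boundary: BoundaryParams = BoundaryParams()
    library: MotifLibrary = MotifLibrary()
    rubric: ScoreRubric = ScoreRubric()
    catalog: FeatureCatalog = field(default_factory=FeatureCatalog)
    formats: tuple[str, ...] = ("tsv", "gff3", "fasta")
    seed: int = 0
    _semantics: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = {
            "window": self.window,
            "edge_distance_nt": self.edge_distance_nt,
            "annotation_e_cutoff": self.annotation_e_cutoff,
            "orf": {
                "start_codons": sorted(self.orf.start_codons),
                "min_len_aa": self.orf.min_len_aa,
                "max_len_aa": self.orf.max_len_aa,
                "require_cys": self.orf.require_cys,
                "genetic_code": self.orf.genetic_code,
            },
            "boundary": {
                "cleavage_motifs": list(self.boundary.cleavage_motifs),
                "st_spacer_min": self.boundary.st_spacer_min,
                "st_spacer_max": self.boundary.st_spacer_max,
                "c_term_exclusion": self.boundary.c_term_exclusion,
            },
            "library": list(self.library.motifs),
            "rubric": {
                "rules": [(r.predicate, r.points, list(r.params)) for r in self.rubric.rules],
                "svm_points": self.rubric.svm_points,
                "threshold": self.rubric.threshold,
            },
            "catalog_version": self.catalog.version,
            "seed": self.seed,
            "files": self._semantics,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        try:
            data = json.loads(path.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            q = q if q.is_absolute() else base / q
            if not q.exists():
                raise ConfigError(f"configured file does not exist: {q}")
            return q

        hmms = data.get("hmms", {})
        missing = [r for r in ("anchor", "class1_n", "class1_c", "class2", "kinase", "class3", "class4") if r not in hmms]
        if missing:
            raise ConfigError(f"config lacks HMM paths for roles: {missing}")
        classifier = ClassifierConfig(
            **{f"{role}_hmm": load_hmm(resolve(p)) for role, p in hmms.items()}
        )
        # the config mapping decides which class a bundle serves, even if it
        # was trained under another label (e.g. one model reused per class)
        import dataclasses

        models = {
            c: dataclasses.replace(SvmModel.load(resolve(p)), lan_class=c)
            for c, p in data.get("models", {}).items()
        }
        annotation = [load_hmm(resolve(p)) for p in data.get("annotation_hmms", [])]
        library = (
            MotifLibrary.from_json(resolve(data["motif_library"]))
            if data.get("motif_library")
            else MotifLibrary()
        )
        rubric = ScoreRubric.from_json(resolve(data["rubric"])) if data.get("rubric") else ScoreRubric()
        orf_cfg = data.get("orf", {})
        orf = OrfParams(
            start_codons=frozenset(orf_cfg.get("start_codons", ("ATG", "GTG", "TTG"))),
            min_len_aa=orf_cfg.get("min_len_aa", 30),
            max_len_aa=orf_cfg.get("max_len_aa", 120),
            require_cys=orf_cfg.get("require_cys", True),
        )
        bd = data.get("boundary", {})
        boundary = BoundaryParams(
            cleavage_motifs=tuple(bd.get("cleavage_motifs", ("GG", "GA"))),
            st_spacer_min=bd.get("st_spacer_min", 2),
            st_spacer_max=bd.get("st_spacer_max", 7),
            c_term_exclusion=bd.get("c_term_exclusion", 10),
        )
        return cls(
            classifier=classifier,
            models=models,
            annotation_models=annotation,
            annotation_e_cutoff=data.get("annotation_e_cutoff", 1e-5),
            window=data.get("window", 7),
            edge_distance_nt=data.get("edge_distance_nt", 3000),
            orf=orf,
            boundary=boundary,
            library=library,
            rubric=rubric,
            formats=tuple(data.get("formats", ("tsv", "gff3", "fasta"))),
            seed=data.get("seed", 0),
            _semantics={k: str(v) for k, v in hmms.items()}
            | {f"model_{k}": str(v) for k, v in data.get("models", {}).items()},
        )


def _protein_index(records: Sequence[GenomeRecord]) -> tuple[list[tuple[str, str]], dict[str, tuple[GenomeRecord, int]]]:
    proteins: list[tuple[str, str]] = []
    where: dict[str, tuple[GenomeRecord, int]] = {}
    for rec in records:
        for i, g in enumerate(rec.genes):
            if not g.protein_seq:
                continue
            pid = g.protein_id or f"{rec.record_id}|{g.locus_id}"
            if pid in where:
                pid = f"{rec.record_id}|{g.locus_id}"
            proteins.append((pid, g.protein_seq))
            where[pid] = (rec, i)
    return proteins, where


def mine_records(records: Sequence[GenomeRecord], config: PipelineConfig) -> MiningReport:
    """Mine already-parsed records (see run_mine for the file-based entry)."""
    proteins, where = _protein_index(records)
    stage = {
        "records": len(records),
        "proteins": len(proteins),
        "anchor_hits": 0,
        "neighborhoods": 0,
        "orfs_enumerated": 0,
        "orfs_filtered": 0,
        "orfs_deduped": 0,
        "precursor_calls": 0,
        "is_precursor": 0,
    }

    anchor_hits = find_lanc_proteins(proteins, config.classifier) if proteins else []
    stage["anchor_hits"] = len(anchor_hits)

    bgc_ids: list[str] = []
    calls: list[BgcCall] = []
    precursors: list = []
    precursor_bgc_ids: list[str] = []
    annotations = []
    per_record_counter: dict[str, int] = {}

    # deterministic order: by record, then gene position
    ordered = sorted(anchor_hits, key=lambda h: (where[h.protein_id][0].record_id, where[h.protein_id][1]))
    for hit in ordered:
        rec, gene_i = where[hit.protein_id]
        nbhd = extract_neighborhood(rec, gene_i, window=config.window, edge_distance_nt=config.edge_distance_nt)
        stage["neighborhoods"] += 1
        n = per_record_counter.get(rec.record_id, 0)
        per_record_counter[rec.record_id] = n + 1
        bgc_id = f"{rec.record_id}_bgc{n}"

        nb_proteins = [
            (g.protein_id or f"{rec.record_id}|{g.locus_id}", g.protein_seq)
            for g in nbhd.genes
            if g.protein_seq
        ]
        nb_hits = hmm_search(list(config.classifier.all_hmms), nb_proteins, e_cutoff=None)
        call = assign_class(nbhd, nb_hits, config.classifier)
        bgc_ids.append(bgc_id)
        calls.append(call)

        span_dna = rec.dna[nbhd.span_start : nbhd.span_end]
        orfs = enumerate_orfs(span_dna, span_offset=nbhd.span_start, params=config.orf, record_id=rec.record_id)
        stage["orfs_enumerated"] += len(orfs)
        kept = filter_orfs(orfs, rec.genes, config.orf)
        stage["orfs_filtered"] += len(kept)
        unique = dedup_by_stop(kept)
        stage["orfs_deduped"] += len(unique)

        model = config.models.get(call.lan_class)
        if model is not None:
            pcalls = call_precursors(call, unique, model, config.rubric, config.library, config.catalog)
            precursors.extend(pcalls)
            precursor_bgc_ids.extend([bgc_id] * len(pcalls))
            stage["precursor_calls"] += len(pcalls)
            stage["is_precursor"] += sum(1 for p in pcalls if p.is_precursor)
        elif call.lan_class != "unclassified":
            logger.info("no SVM model for class %s; skipping precursor scoring of %s", call.lan_class, bgc_id)

        annotations.append(
            annotate_genes(call, list(config.annotation_models), config.annotation_e_cutoff, bgc_id=bgc_id)
        )

    for key, value in stage.items():
        logger.info("stage %-18s %d", key, value)

    report = summarize(calls, precursors, records, bgc_ids=bgc_ids, precursor_bgc_ids=precursor_bgc_ids)
    report.census = census(annotations, calls)
    report.config_hash = config.config_hash()
    report.stage_counts = stage
    return report


def run_mine(inputs: Sequence[str | Path], config: PipelineConfig) -> MiningReport:
    """Mine GenBank files end to end; unparseable records are skipped with a
    logged warning, but if every input fails the run aborts."""
    records: list[GenomeRecord] = []
    digests: dict[str, str] = {}
    failures = 0
    for path in inputs:
        try:
            recs = read_genbank(path)
            if not recs:
                raise ValueError("no LOCUS records found")
        except Exception as exc:  # per-record parse failure: skip, continue
            logger.warning("skipping unparseable input %s: %s", path, exc)
            failures += 1
            continue
        records.extend(recs)
        digests[str(path)] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    if inputs and failures == len(inputs):
        raise InputError("no input file could be parsed")
    report = mine_records(records, config)
    report.input_digests = digests
    return report


def run_train(
    labeled_fasta: str | Path,
    lan_class: str,
    cfg: TrainingConfig = TrainingConfig(),
    catalog: FeatureCatalog | None = None,
    library: MotifLibrary | None = None,
    out_path: str | Path | None = None,
) -> tuple[SvmModel, dict]:
    """Train a per-class SVM from a labeled FASTA (label=1|0 in headers).

    Returns the model and a training report (selected feature names, CV
    accuracy, seed); writes the model bundle when out_path is given.
    """
    from lanminer.fixtures import read_labeled_fasta

    catalog = catalog or FeatureCatalog()
    library = library or MotifLibrary()
    peptides = read_labeled_fasta(labeled_fasta)
    labels = {label for _, _, label in peptides}
    if len(labels) < 2:
        raise ValueError("training input contains a single class; need both labels")
    X, y, kept = prepare_training_matrix(peptides, library, catalog)
    if len(set(y)) < 2:
        raise ValueError("one label was entirely rejected at the boundary step")
    mask = select_features(X, y, cfg)
    if not mask.any():
        raise ValueError(
            "ANOVA selected zero features at alpha="
            f"{cfg.anova_alpha}; raise alpha or provide more separable data"
        )
    model = train_svm(X, y, mask, cfg, lan_class=lan_class, catalog_version=catalog.version)
    train_report = {
        "lan_class": lan_class,
        "n_input": len(peptides),
        "n_used": len(kept),
        "n_selected_features": int(mask.sum()),
        "selected_features": [catalog.feature_names[i] for i in range(len(mask)) if mask[i]][:200],
        "cv_accuracy": model.cv_accuracy,
        "hyperparameters": model.hyperparameters,
        "seed": cfg.seed,
    }
    if out_path is not None:
        model.save(out_path)
        Path(str(out_path) + ".report.json").write_text(json.dumps(train_report, indent=1))
    return model, train_report


def report_to_jsonable(report: MiningReport) -> dict:
    """Machine-readable run summary (written alongside the TSV outputs)."""
    return {
        "config_hash": report.config_hash,
        "input_digests": report.input_digests,
        "stage_counts": report.stage_counts,
        "class_counts": report.class_counts,
        "precursor_class_counts": report.precursor_class_counts,
        "phylum_counts": report.phylum_counts,
        "gg_leader_fraction": report.gg_leader_fraction,
        "precursors_per_bgc_hist": {str(k): v for k, v in report.precursors_per_bgc_hist.items()},
        "gc_pairs": [[bid, round(a, 6), round(b, 6)] for bid, a, b in report.gc_pairs],
        "bgcs": [
            {
                "bgc_id": bid,
                "record_id": c.neighborhood.record_id,
                "lan_class": c.lan_class,
                "anchor": c.neighborhood.anchor.protein_id or c.neighborhood.anchor.locus_id,
                "span": [c.neighborhood.span_start, c.neighborhood.span_end],
                "contig_edge": c.contig_edge,
                "multi_class_flag": c.multi_class_flag,
            }
            for bid, c in report.bgc_calls
        ],
        "census": [
            {"name": r.name, "total": r.total, "per_class": dict(r.per_class)}
            for r in (report.census.rows if report.census else [])
        ],
    }


def write_outputs(report: MiningReport, out_dir: str | Path, formats: Sequence[str]) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome_io.write_report(report, out_dir, formats)
    if report.census is not None:
        (out_dir / "census.tsv").write_text(report.census.as_tsv())
    with open(out_dir / "gc_pairs.tsv", "w") as fh:
        fh.write("bgc_id\tbgc_gc\tgenome_gc\n")
        for bid, a, b in report.gc_pairs:
            fh.write(f"{bid}\t{a:.6f}\t{b:.6f}\n")
    (out_dir / "run_summary.json").write_text(json.dumps(report_to_jsonable(report), indent=1, sort_keys=True))
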