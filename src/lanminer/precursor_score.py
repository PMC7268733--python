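"""Leader/core splitting, featurization, ANOVA-selected SVM, and rubric scoring.

The leader-core boundary is estimated by searching residues after the leader
motif (or the whole peptide when no motif is found) for GG, GA, or
S/T(x){2-7}C occurrences: the core starts immediately after a GG/GA, or one
residue before the S/T. Occurrences starting within 10 residues of the
C-terminus are ignored; among qualifying occurrences the one giving the
longest core wins; with none, the C-terminal half is the core. A peptide
whose chosen core lacks Cys is rejected as a candidate.
"""

from __future__ import annotations

import pickle
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from lanminer.bgc_classify import BgcCall
from lanminer.orf_extract import CandidateOrf

AA20 = "ACDEFGHIKLMNPQRSTVWY"

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DEFAULT_MOTIFS: tuple[tuple[str, str], ...] = (
    ("FxLD", r"F.LD"),
    ("LxLxKx5L", r"L.L.K.{5}L"),
    ("LxLQ", r"L.LQ"),
    ("ED-LM", r"[ED][LM]"),
    ("GG-terminal", r"GG"),
)


@dataclass(frozen=True)
class MotifLibrary:
    """Named leader-peptide motifs as regular expressions over amino acids."""

    motifs: tuple[tuple[str, str], ...] = DEFAULT_MOTIFS

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("motif library must be non-empty")
        for _, pattern in self.motifs:
            re.compile(pattern)

    @classmethod
    def from_json(cls, path: str | Path) -> "MotifLibrary":
        import json

        entries = json.loads(Path(path).read_text())
        return cls(motifs=tuple((e["name"], e["pattern"]) for e in entries))


@dataclass(frozen=True)
class BoundaryParams:
    cleavage_motifs: tuple[str, ...] = ("GG", "GA")
    st_spacer_min: int = 2
    st_spacer_max: int = 7
    c_term_exclusion: int = 10
    min_leader: int = 1

    def __post_init__(self) -> None:
        if self.st_spacer_min > self.st_spacer_max:
            raise ValueError("st_spacer_min > st_spacer_max")


@dataclass(frozen=True)
class BoundaryCall:
    peptide: str
    boundary: int  # core starts here (0-based)
    rule_used: str  # GG | GA | STC | fallback-half
    motif_name: str | None = None

    @property
    def leader(self) -> str:
        return self.peptide[: self.boundary]

    @property
    def core(self) -> str:
        return self.peptide[self.boundary :]


def match_leader_motif(
    peptide: str, library: MotifLibrary = MotifLibrary()
) -> tuple[str, int] | None:
    """Best library motif in the N-terminal two-thirds of the peptide.

    Returns (motif_name, match_end_index) with an exclusive end index, or
    None. Longer matches outrank shorter ones; ties break by library order,
    then by leftmost position.
    """
    if not peptide:
        raise ValueError("empty peptide")
    limit = (2 * len(peptide)) // 3
    best: tuple[int, int, int, str] | None = None  # (-len, lib_idx, start, name)
    best_end = -1
    for idx, (name, pattern) in enumerate(library.motifs):
        for m in re.finditer(pattern, peptide):
            if m.end() > limit:
                continue
            key = (-(m.end() - m.start()), idx, m.start(), name)
            if best is None or key < best:
                best = key
                best_end = m.end()
    if best is None:
        return None
    return best[3], best_end


def _boundary_candidates(peptide: str, search_start: int, params: BoundaryParams) -> list[tuple[int, str]]:
    """All qualifying (boundary, rule) pairs in deterministic rule order."""
    L = len(peptide)
    out: list[tuple[int, str]] = []
    for i in range(search_start, L - 1):
        if i >= L - params.c_term_exclusion:
            break
        pair = peptide[i : i + 2]
        if pair in params.cleavage_motifs and i + 2 >= params.min_leader:
            out.append((i + 2, pair))
    for k in range(max(search_start, params.min_leader + 1), L):
        if k >= L - params.c_term_exclusion:
            break
        if peptide[k] not in "ST":
            continue
        lo, hi = k + 1 + params.st_spacer_min, k + 1 + params.st_spacer_max
        if "C" in peptide[lo : min(hi + 1, L)]:
            out.append((k - 1, "STC"))
    return out


def split_leader_core(
    peptide: str,
    motif_hit: tuple[str, int] | None = None,
    params: BoundaryParams = BoundaryParams(),
) -> BoundaryCall | None:
    """Estimate the leader-core boundary; None means the peptide is rejected.

    Rejection (a typed outcome, not an exception) occurs when the chosen
    core contains no Cys.
    """
    if len(peptide) < 4:
        raise ValueError("peptide too short to split")
    motif_name = motif_hit[0] if motif_hit else None
    search_start = motif_hit[1] if motif_hit else 0
    candidates = _boundary_candidates(peptide, search_start, params)
    if candidates:
        boundary, rule = min(candidates, key=lambda c: (c[0], _rule_rank(c[1])))
    else:
        boundary, rule = len(peptide) // 2, "fallback-half"
    if "C" not in peptide[boundary:]:
        return None
    return BoundaryCall(peptide=peptide, boundary=boundary, rule_used=rule, motif_name=motif_name)


def _rule_rank(rule: str) -> int:
    return {"GG": 0, "GA": 1, "STC": 2}.get(rule, 3)


# ---------------------------------------------------------------------------
# feature catalog


class FeatureCatalog:
    """Versioned, ordered list of per-region peptide features.

    Per region (leader/core/full): residue counts and frequencies (20+20),
    dipeptide frequencies (400), length, Ser/Thr/Cys counts, S+T+C fraction,
    net charge (K+R-D-E), mean Kyte-Doolittle hydropathy, aromaticity —
    plus one leader-motif indicator per library motif.
    """

    REGIONS = ("leader", "core", "full")

    def __init__(self, version: str = "default-1", library: MotifLibrary | None = None):
        self.version = version
        self.library = library or MotifLibrary()
        names: list[str] = []
        for region in self.REGIONS:
            names += [f"{region}_count_{a}" for a in AA20]
            names += [f"{region}_freq_{a}" for a in AA20]
            names += [f"{region}_di_{a}{b}" for a in AA20 for b in AA20]
            names += [
                f"{region}_length",
                f"{region}_ser_count",
                f"{region}_thr_count",
                f"{region}_cys_count",
                f"{region}_stc_fraction",
                f"{region}_net_charge",
                f"{region}_mean_hydropathy",
                f"{region}_aromaticity",
            ]
        names += [f"motif_{name}" for name, _ in self.library.motifs]
        self.feature_names: tuple[str, ...] = tuple(names)

    def __len__(self) -> int:
        return len(self.feature_names)

    def index(self, name: str) -> int:
        return self.feature_names.index(name)


def _region_features(seq: str) -> list[float]:
    n = len(seq)
    counts = [seq.count(a) for a in AA20]
    freqs = [c / n if n else 0.0 for c in counts]
    di = np.zeros((20, 20))
    pos = {a: i for i, a in enumerate(AA20)}
    for i in range(n - 1):
        a, b = seq[i], seq[i + 1]
        if a in pos and b in pos:
            di[pos[a], pos[b]] += 1
    if n > 1:
        di /= n - 1
    s, t, c = seq.count("S"), seq.count("T"), seq.count("C")
    charge = seq.count("K") + seq.count("R") - seq.count("D") - seq.count("E")
    hydro = sum(KYTE_DOOLITTLE.get(a, 0.0) for a in seq) / n if n else 0.0
    arom = sum(seq.count(a) for a in "FWY") / n if n else 0.0
    return (
        [float(x) for x in counts]
        + freqs
        + [float(x) for x in di.ravel()]
        + [float(n), float(s), float(t), float(c), (s + t + c) / n if n else 0.0, float(charge), hydro, arom]
    )


def compute_features(call: BoundaryCall, catalog: FeatureCatalog) -> np.ndarray:
    """Deterministic numeric vector aligned to the catalog order."""
    values: list[float] = []
    for region in FeatureCatalog.REGIONS:
        seq = {"leader": call.leader, "core": call.core, "full": call.peptide}[region]
        values += _region_features(seq)
    for _, pattern in catalog.library.motifs:
        values.append(1.0 if re.search(pattern, call.leader) else 0.0)
    vec = np.asarray(values, dtype=float)
    if len(vec) != len(catalog):
        raise AssertionError("feature vector misaligned with catalog")
    return vec


# ---------------------------------------------------------------------------
# feature selection and SVM


@dataclass(frozen=True)
class TrainingConfig:
    anova_alpha: float = 0.05
    cv_folds: int = 5
    seed: int = 0
    kernel: str = "rbf"
    grid: Mapping[str, Sequence] = field(
        default_factory=lambda: {"C": (1.0, 10.0), "gamma": ("scale",)}
    )

    def __post_init__(self) -> None:
        if not 0 < self.anova_alpha < 1:
            raise ValueError("anova_alpha must be in (0, 1)")


def anova_f_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature one-way ANOVA F statistic and p-value between label groups."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = [X[y == lab] for lab in np.unique(y)]
    if len(groups) < 2:
        raise ValueError("need at least two label groups")
    res = stats.f_oneway(*groups, axis=0)
    return np.asarray(res.statistic), np.asarray(res.pvalue)


def select_features(X: np.ndarray, y: np.ndarray, cfg: TrainingConfig = TrainingConfig()) -> np.ndarray:
    """Boolean mask of features with ANOVA p strictly below anova_alpha.

    Zero-variance features are dropped (mask False) before testing.
    """
    X = np.asarray(X, dtype=float)
    variable = X.var(axis=0) > 0
    if not variable.any():
        raise ValueError("all features are constant")
    mask = np.zeros(X.shape[1], dtype=bool)
    _, pvals = anova_f_pvalues(X[:, variable], y)
    mask[variable] = np.nan_to_num(pvals, nan=1.0) < cfg.anova_alpha
    return mask


@dataclass
class SvmModel:
    """Trained SVM plus the preprocessing needed to apply it to raw vectors."""

    lan_class: str
    catalog_version: str
    selected_mask: np.ndarray
    scaler: StandardScaler
    svc: SVC
    kernel: str
    hyperparameters: dict
    decision_threshold: float
    cv_accuracy: float
    n_pos: int
    n_neg: int
    seed: int

    def decision_margin(self, vec: np.ndarray) -> float:
        x = np.asarray(vec, dtype=float)[self.selected_mask].reshape(1, -1)
        return float(self.svc.decision_function(self.scaler.transform(x))[0])

    def predict(self, vec: np.ndarray) -> bool:
        return self.decision_margin(vec) > self.decision_threshold

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh, protocol=4)

    @staticmethod
    def load(path: str | Path) -> "SvmModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, SvmModel):
            raise TypeError("not an SvmModel bundle")
        return model


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    cfg: TrainingConfig = TrainingConfig(),
    lan_class: str = "II",
    catalog_version: str = "default-1",
) -> SvmModel:
    """Fit a standardized SVM on the ANOVA-selected features.

    Hyperparameters come from a fixed-seed cross-validated grid search;
    the reported cv_accuracy is the best mean CV score.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    labels = np.unique(y)
    if len(labels) < 2:
        raise ValueError("training data contains a single class")
    if not mask.any():
        raise ValueError("no features selected; lower the ANOVA threshold or add data")
    Xs = X[:, mask]
    scaler = StandardScaler().fit(Xs)
    Xz = scaler.transform(Xs)
    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    search = GridSearchCV(
        SVC(kernel=cfg.kernel, random_state=cfg.seed),
        param_grid=dict(cfg.grid),
        cv=cv,
        scoring="accuracy",
        n_jobs=1,
    )
    search.fit(Xz, y)
    return SvmModel(
        lan_class=lan_class,
        catalog_version=catalog_version,
        selected_mask=np.asarray(mask, dtype=bool),
        scaler=scaler,
        svc=search.best_estimator_,
        kernel=cfg.kernel,
        hyperparameters=dict(search.best_params_),
        decision_threshold=0.0,
        cv_accuracy=float(search.best_score_),
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# rubric


@dataclass(frozen=True)
class RubricContext:
    bgc: BgcCall | None = None
    orf: CandidateOrf | None = None


def _pred_motif_present(call: BoundaryCall, ctx: RubricContext, params: Mapping) -> bool:
    return call.motif_name is not None


def _pred_gg_ga_boundary(call: BoundaryCall, ctx: RubricContext, params: Mapping) -> bool:
    return call.rule_used in ("GG", "GA")


def _pred_core_stc_fraction(call: BoundaryCall, ctx: RubricContext, params: Mapping) -> bool:
    core = call.core
    frac = sum(core.count(a) for a in "STC") / len(core) if core else 0.0
    return frac >= params.get("min_fraction", 0.2)


def _pred_adjacent_codirectional(call: BoundaryCall, ctx: RubricContext, params: Mapping) -> bool:
    """ORF on the same strand as a class-defining gene, with no annotated
    gene lying entirely between them."""
    if ctx.bgc is None or ctx.orf is None or not ctx.bgc.class_genes:
        return False
    orf = ctx.orf
    for gene in ctx.bgc.class_genes:
        if gene.strand != orf.strand:
            continue
        lo = min(orf.end, gene.end)
        hi = max(orf.start, gene.start)
        if lo >= hi:  # intervals overlap or touch
            return True
        between = any(
            g.start >= lo and g.end <= hi and (g.start, g.end) != (gene.start, gene.end)
            for g in ctx.bgc.neighborhood.genes
        )
        if not between:
            return True
    return False


PREDICATES: dict[str, Callable[[BoundaryCall, RubricContext, Mapping], bool]] = {
    "leader_motif_present": _pred_motif_present,
    "gg_ga_boundary": _pred_gg_ga_boundary,
    "core_stc_fraction": _pred_core_stc_fraction,
    "adjacent_codirectional": _pred_adjacent_codirectional,
}


@dataclass(frozen=True)
class RubricRule:
    description: str
    predicate: str
    points: int
    params: tuple = ()  # (key, value) pairs, hashable

    def fires(self, call: BoundaryCall, ctx: RubricContext) -> bool:
        return PREDICATES[self.predicate](call, ctx, dict(self.params))


DEFAULT_RULES: tuple[RubricRule, ...] = (
    RubricRule("leader motif present", "leader_motif_present", 3),
    RubricRule("GG/GA cleavage boundary", "gg_ga_boundary", 2),
    RubricRule("core S+T+C fraction >= 0.2", "core_stc_fraction", 2, (("min_fraction", 0.2),)),
    RubricRule("adjacent and co-directional with class-defining gene", "adjacent_codirectional", 2),
)


@dataclass(frozen=True)
class ScoreRubric:
    rules: tuple[RubricRule, ...] = DEFAULT_RULES
    svm_points: int = 10
    threshold: int = 10

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreRubric":
        import json

        data = json.loads(Path(path).read_text())
        rules = tuple(
            RubricRule(
                description=r.get("description", r["predicate"]),
                predicate=r["predicate"],
                points=int(r["points"]),
                params=tuple(sorted(r.get("params", {}).items())),
            )
            for r in data.get("rules", [])
        )
        return cls(rules=rules, svm_points=int(data["svm_points"]), threshold=int(data["threshold"]))


def apply_rubric(
    call: BoundaryCall,
    context: RubricContext,
    svm_decision: bool,
    rubric: ScoreRubric = ScoreRubric(),
) -> tuple[int, int]:
    """Return (rubric_points, total_score); total adds svm_points on a
    positive SVM decision."""
    points = sum(rule.points for rule in rubric.rules if rule.fires(call, context))
    total = points + (rubric.svm_points if svm_decision else 0)
    return points, total


# ---------------------------------------------------------------------------
# per-BGC precursor calling


@dataclass(frozen=True)
class PrecursorCall:
    orf: CandidateOrf
    boundary: BoundaryCall
    features: np.ndarray
    svm_decision: bool
    svm_margin: float
    rubric_points: int
    total_score: int
    is_precursor: bool


def call_precursors(
    bgc: BgcCall,
    orfs: Sequence[CandidateOrf],
    model: SvmModel,
    rubric: ScoreRubric = ScoreRubric(),
    library: MotifLibrary = MotifLibrary(),
    catalog: FeatureCatalog | None = None,
) -> list[PrecursorCall]:
    """Run motif -> boundary -> features -> SVM -> rubric for each ORF.

    Boundary-rejected ORFs (no core Cys) are dropped. Calls are sorted by
    descending total score.
    """
    if model.lan_class != bgc.lan_class:
        raise ValueError(f"model class {model.lan_class} != BGC class {bgc.lan_class}")
    catalog = catalog or FeatureCatalog(version=model.catalog_version)
    if catalog.version != model.catalog_version:
        raise ValueError("catalog version does not match the model")
    calls: list[PrecursorCall] = []
    for orf in orfs:
        hit = match_leader_motif(orf.aa_seq, library)
        boundary = split_leader_core(orf.aa_seq, hit)
        if boundary is None:
            continue
        vec = compute_features(boundary, catalog)
        margin = model.decision_margin(vec)
        decision = margin > model.decision_threshold
        ctx = RubricContext(bgc=bgc, orf=orf)
        points, total = apply_rubric(boundary, ctx, decision, rubric)
        calls.append(
            PrecursorCall(
                orf=orf,
                boundary=boundary,
                features=vec,
                svm_decision=decision,
                svm_margin=margin,
                rubric_points=points,
                total_score=total,
                is_precursor=total >= rubric.threshold,
            )
        )
    calls.sort(key=lambda c: (-c.total_score, c.orf.start, c.orf.strand))
    return calls


def prepare_training_matrix(
    peptides: Sequence[tuple[str, str, int]],
    library: MotifLibrary = MotifLibrary(),
    catalog: FeatureCatalog | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Boundary-split and featurize labeled peptides (id, sequence, label).

    Peptides rejected by the boundary step are dropped; returns X, y and the
    surviving ids.
    """
    catalog = catalog or FeatureCatalog()
    rows, labels, kept = [], [], []
    for pid, seq, label in peptides:
        hit = match_leader_motif(seq, library)
        call = split_leader_core(seq, hit)
        if call is None:
            continue
        rows.append(compute_features(call, catalog))
        labels.append(int(label))
        kept.append(pid)
    if not rows:
        raise ValueError("no peptides survived boundary splitting")
    return np.vstack(rows), np.asarray(labels), kept
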