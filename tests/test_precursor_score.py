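import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lanminer.fixtures import make_precursor_peptide, make_training_peptides
from lanminer.precursor_score import (
    BoundaryCall,
    FeatureCatalog,
    MotifLibrary,
    RubricContext,
    ScoreRubric,
    RubricRule,
    TrainingConfig,
    anova_f_pvalues,
    apply_rubric,
    compute_features,
    match_leader_motif,
    prepare_training_matrix,
    select_features,
    split_leader_core,
    train_svm,
)

from oracles import oracle_anova_p, oracle_split

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestMotif:
    def test_fxld_match_ends_at_d(self):
        peptide = "MSKFELDLAGAQTESILAGGASHWCTCCTTSSC"
        hit = match_leader_motif(peptide)
        assert hit is not None
        name, end = hit
        assert name == "FxLD"
        assert peptide[end - 1] == "D"

    def test_poly_a_no_match(self):
        assert match_leader_motif("A" * 40) is None

    def test_match_restricted_to_n_terminal_two_thirds(self):
        # the only motif occurrence sits in the C-terminal third
        peptide = "M" + "A" * 30 + "FELD" + "A" * 5
        assert match_leader_motif(peptide) is None

    def test_planted_motif_index_recovered(self):
        rng = random.Random(21)
        for _ in range(100):
            planted = make_precursor_peptide(rng, motif="FxLD", cleavage="GG")
            hit = match_leader_motif(planted.aa_seq)
            assert hit is not None and hit[0] == "FxLD"
            # the matched window is genuinely an FxLD occurrence
            s = planted.aa_seq[hit[1] - 4 : hit[1]]
            assert s[0] == "F" and s[2:] == "LD"

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError):
            match_leader_motif("")


class TestBoundary:
    def test_gg_boundary(self):
        # GG ending at index 19 -> core starts at 20
        peptide = "M" + "A" * 17 + "GG" + "L" + "C" * 39
        call = split_leader_core(peptide, None)
        assert call is not None
        assert call.boundary == 20
        assert call.rule_used == "GG"
        assert call.leader.endswith("GG")

    def test_fallback_half_even(self):
        leader = "MALEVKIRHQNFWEYVILPQRKNEHMALEVKI"
        core = "AILVCPQRKNEHWEYAILVPQRKNEHWEYAIL"
        peptide = leader + core
        assert len(peptide) == 64 and not set(peptide) & set("GST")
        call = split_leader_core(peptide, None)
        assert call is not None
        assert call.rule_used == "fallback-half"
        assert len(call.leader) == 32 and len(call.core) == 32

    def test_fallback_half_odd_core_gets_extra(self):
        peptide = "MALEVKIRHQNFWEYVILPQRKNEHMALEVKI" + "AILVCPQRKNEHWEYAILVPQRKNEHWEYAILV"
        assert len(peptide) == 65 and not set(peptide) & set("GST")
        call = split_leader_core(peptide, None)
        assert call is not None
        assert call.rule_used == "fallback-half"
        assert len(call.leader) == 32 and len(call.core) == 33

    def test_longest_core_wins(self):
        # GG at 12-13 and GA at 30-31: GG gives the longer core
        peptide = "M" + "L" * 11 + "GG" + "L" * 16 + "GA" + "L" * 10 + "CCCCCCCCCCCC"
        call = split_leader_core(peptide, None)
        assert call is not None
        assert call.boundary == 14
        assert call.rule_used == "GG"

    def test_stc_rule_boundary_one_before_st(self):
        k = 14
        peptide = "M" + "L" * (k - 1) + "TAAC" + "L" * 6 + "CCCCCCCCCC"
        assert peptide[k] == "T" and peptide[k + 3] == "C"
        call = split_leader_core(peptide, None)
        assert call is not None
        assert call.boundary == k - 1
        assert call.rule_used == "STC"

    def test_c_terminal_exclusion(self):
        # GG whose first G is 8 residues from the end is ignored
        peptide = "M" + "L" * 30 + "C" * 5 + "GG" + "LLCLLLLL"
        L = len(peptide)
        gg_start = peptide.rindex("GG")
        assert gg_start >= L - 10
        call = split_leader_core(peptide, None)
        assert call is not None
        assert call.rule_used == "fallback-half"

    def test_core_without_cys_rejected(self):
        peptide = "M" + "L" * 20 + "GG" + "A" * 20
        assert split_leader_core(peptide, None) is None

    def test_search_starts_after_motif(self):
        # GG before the motif end is not a candidate
        peptide = "MGG" + "FALD" + "L" * 20 + "GG" + "C" * 15
        hit = match_leader_motif(peptide)
        assert hit is not None and hit[0] == "FxLD"
        call = split_leader_core(peptide, hit)
        assert call is not None
        assert call.boundary == peptide.rindex("GG") + 2

    def test_concatenation_identity_fuzzed(self):
        rng = random.Random(5)
        for _ in range(2000):
            peptide = "".join(rng.choice(AA) for _ in range(rng.randint(4, 90)))
            hit = match_leader_motif(peptide) if len(peptide) > 0 else None
            call = split_leader_core(peptide, hit)
            if call is not None:
                assert call.leader + call.core == peptide

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence(self, seed):
        rng = random.Random(seed)
        for _ in range(100):
            peptide = "".join(rng.choice(AA) for _ in range(rng.randint(4, 100)))
            start = rng.choice([0, 0, rng.randint(0, max(0, len(peptide) - 1))])
            got = split_leader_core(peptide, ("x", start) if start else None)
            expected = oracle_split(peptide, search_start=start)
            if expected is None:
                assert got is None
            else:
                assert got is not None
                assert (got.boundary, got.rule_used) == expected

    def test_too_short_peptide_raises(self):
        with pytest.raises(ValueError):
            split_leader_core("MAC", None)


class TestFeatures:
    def test_core_sstc_hand_count(self):
        catalog = FeatureCatalog()
        call = BoundaryCall(peptide="MKLASSTC", boundary=4, rule_used="GG")
        assert call.core == "SSTC"
        vec = compute_features(call, catalog)
        assert vec[catalog.index("core_ser_count")] == 2
        assert vec[catalog.index("core_thr_count")] == 1
        assert vec[catalog.index("core_cys_count")] == 1
        assert vec[catalog.index("core_stc_fraction")] == 1.0
        assert vec[catalog.index("core_count_S")] == 2

    def test_single_residue_leader_defined(self):
        catalog = FeatureCatalog()
        call = BoundaryCall(peptide="MSSTCSSTC", boundary=1, rule_used="STC")
        vec = compute_features(call, catalog)
        assert np.all(np.isfinite(vec))

    def test_frequencies_sum_to_one(self):
        catalog = FeatureCatalog()
        call = BoundaryCall(peptide="MKLFELDAGGSSTCWTC", boundary=10, rule_used="GG")
        vec = compute_features(call, catalog)
        for region in ("leader", "core", "full"):
            aa_sum = sum(vec[catalog.index(f"{region}_freq_{a}")] for a in AA)
            di_sum = sum(
                vec[catalog.index(f"{region}_di_{a}{b}")] for a in AA for b in AA
            )
            assert aa_sum == pytest.approx(1.0)
            assert di_sum == pytest.approx(1.0)

    def test_dipeptide_counting_oracle(self):
        catalog = FeatureCatalog()
        rng = random.Random(11)
        for _ in range(50):
            pep = "".join(rng.choice(AA) for _ in range(rng.randint(6, 60)))
            b = rng.randint(1, len(pep) - 1)
            call = BoundaryCall(peptide=pep, boundary=b, rule_used="GG")
            vec = compute_features(call, catalog)
            for region, seq in (("leader", call.leader), ("core", call.core), ("full", pep)):
                # independent sliding-window count
                for pair in {seq[i : i + 2] for i in range(len(seq) - 1)}:
                    want = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == pair)
                    got = vec[catalog.index(f"{region}_di_{pair}")] * (len(seq) - 1)
                    assert got == pytest.approx(want)

    def test_net_charge(self):
        catalog = FeatureCatalog()
        call = BoundaryCall(peptide="MKRDEKC", boundary=1, rule_used="GG")
        vec = compute_features(call, catalog)
        # core KRDEKC: K+R+K=3, D+E=2 -> +1
        assert vec[catalog.index("core_net_charge")] == 1.0

    def test_catalog_size_and_order_stable(self):
        c1, c2 = FeatureCatalog(), FeatureCatalog()
        assert c1.feature_names == c2.feature_names
        assert len(c1) == len(c1.feature_names)


class TestSelectFeatures:
    def test_pvalues_match_closed_form(self):
        g0 = [[1.0, 2.0], [1.2, 2.2], [0.9, 1.7], [1.1, 2.4]]
        g1 = [[2.0, 2.1], [2.2, 2.3], [1.9, 1.8], [2.1, 2.2]]
        X = np.array(g0 + g1)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        _, pvals = anova_f_pvalues(X, y)
        for j in range(2):
            expected = oracle_anova_p([[row[j] for row in g0], [row[j] for row in g1]])
            assert pvals[j] == pytest.approx(expected, abs=1e-9)

    def test_constant_feature_dropped(self):
        X = np.array([[1.0, 5.0], [1.0, 6.0], [1.0, 1.0], [1.0, 2.0]])
        y = np.array([0, 0, 1, 1])
        mask = select_features(X, y, TrainingConfig(anova_alpha=0.5))
        assert mask[0] == False  # noqa: E712  constant -> excluded

    def test_all_constant_raises(self):
        X = np.ones((6, 3))
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError):
            select_features(X, y)

    def test_separated_feature_selected(self):
        rng = np.random.default_rng(0)
        n = 50
        x0 = rng.normal(0.0, 1.0, n)
        x1 = rng.normal(3.0, 1.0, n)  # separation 3 pooled-sd
        noise = rng.normal(0.0, 1.0, 2 * n)
        X = np.column_stack([np.concatenate([x0, x1]), noise])
        y = np.array([0] * n + [1] * n)
        mask = select_features(X, y)
        assert mask[0] == True  # noqa: E712

    def test_strict_alpha_boundary(self):
        # construct data, then set alpha exactly to the observed p: strict
        # inequality must exclude the feature
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 1))
        y = np.array([0] * 10 + [1] * 10)
        _, pvals = anova_f_pvalues(X, y)
        p = float(pvals[0])
        mask = select_features(X, y, TrainingConfig(anova_alpha=p))
        assert mask[0] == False  # noqa: E712
        mask = select_features(X, y, TrainingConfig(anova_alpha=min(1 - 1e-12, p * 1.000001)))
        assert mask[0] == True  # noqa: E712


class TestTrainSvm:
    def test_linearly_separable_perfect_training(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]] * 5)
        y = np.array([0, 0, 0, 1, 1, 1] * 5)
        model = train_svm(X, y, np.array([True]), TrainingConfig(cv_folds=3))
        preds = [model.predict(np.array([v])) for v in (0.05, 5.05)]
        assert preds == [False, True]

    def test_single_class_raises(self):
        X = np.ones((10, 2)) + np.arange(20).reshape(10, 2)
        with pytest.raises(ValueError):
            train_svm(X, np.ones(10), np.array([True, True]))

    def test_gaussian_separation_cv_accuracy(self):
        rng = np.random.default_rng(7)
        n = 100
        X0 = rng.normal(0.0, 1.0, (n, 5))
        X1 = rng.normal(0.0, 1.0, (n, 5))
        X1[:, 0] += 3.0
        X = np.vstack([X0, X1])
        y = np.array([0] * n + [1] * n)
        model = train_svm(X, y, np.ones(5, dtype=bool), TrainingConfig(seed=0))
        assert model.cv_accuracy >= 0.95

    def test_permutation_null_cv_accuracy(self):
        rng = np.random.default_rng(8)
        n = 100
        X = rng.normal(size=(2 * n, 5))
        y = rng.permutation([0] * n + [1] * n)
        model = train_svm(X, y, np.ones(5, dtype=bool), TrainingConfig(seed=0))
        assert abs(model.cv_accuracy - 0.5) <= 0.12

    def test_model_save_load_roundtrip(self, tmp_path, trained_svm):
        p = tmp_path / "m.bundle"
        trained_svm.save(p)
        from lanminer.precursor_score import SvmModel

        loaded = SvmModel.load(p)
        vec = np.zeros(len(trained_svm.selected_mask))
        assert loaded.decision_margin(vec) == trained_svm.decision_margin(vec)


class TestRubric:
    def _call(self, motif=None, rule="GG", core="SSTCAAAA"):
        leader = "M" + "A" * 10
        return BoundaryCall(peptide=leader + core, boundary=len(leader), rule_used=rule, motif_name=motif)

    def test_empty_rubric_negative_svm(self):
        rubric = ScoreRubric(rules=(), svm_points=10, threshold=10)
        points, total = apply_rubric(self._call(), RubricContext(), False, rubric)
        assert (points, total) == (0, 0)

    def test_svm_only(self):
        rubric = ScoreRubric(rules=(), svm_points=10, threshold=10)
        points, total = apply_rubric(self._call(), RubricContext(), True, rubric)
        assert (points, total) == (0, 10)

    def test_default_rubric_hand_audit(self):
        call = self._call(motif="FxLD", rule="GG", core="SSTCAAAA")
        # fired: motif(+3), GG boundary(+2), core stc 4/8 >= 0.2 (+2); no context
        points, total = apply_rubric(call, RubricContext(), True)
        assert points == 7
        assert total == 17

    def test_monotonicity_extra_positive_rule(self):
        call = self._call(motif="FxLD")
        base = ScoreRubric(rules=(), svm_points=10, threshold=10)
        more = ScoreRubric(
            rules=(RubricRule("motif", "leader_motif_present", 3),), svm_points=10, threshold=10
        )
        _, t0 = apply_rubric(call, RubricContext(), True, base)
        _, t1 = apply_rubric(call, RubricContext(), True, more)
        assert t1 >= t0

    def test_rubric_json_roundtrip(self, tmp_path):
        import json

        payload = {
            "rules": [
                {"predicate": "leader_motif_present", "points": 3},
                {"predicate": "core_stc_fraction", "points": 2, "params": {"min_fraction": 0.3}},
            ],
            "svm_points": 8,
            "threshold": 9,
        }
        p = tmp_path / "rubric.json"
        p.write_text(json.dumps(payload))
        rubric = ScoreRubric.from_json(p)
        assert rubric.svm_points == 8 and rubric.threshold == 9
        assert len(rubric.rules) == 2


class TestEndToEndScoring:
    def test_training_peptides_recovered(self):
        peptides = make_training_peptides(60, 60, separation=4.0, seed=2)
        X, y, kept = prepare_training_matrix(peptides)
        mask = select_features(X, y)
        catalog = FeatureCatalog()
        assert mask[catalog.index("core_cys_count")] or mask[catalog.index("core_count_C")]
        model = train_svm(X, y, mask, TrainingConfig(seed=0))
        assert model.cv_accuracy >= 0.95

    def test_call_precursors_class_mismatch_raises(self, svm_per_class, pipeline_config, fixture_genome):
        import dataclasses

        from lanminer.pipeline import mine_records
        from lanminer.precursor_score import call_precursors

        record, _ = fixture_genome
        report = mine_records([record], pipeline_config)
        _, bgc = report.bgc_calls[0]
        wrong = svm_per_class["II" if bgc.lan_class != "II" else "III"]
        with pytest.raises(ValueError):
            call_precursors(bgc, [], wrong)
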