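import dataclasses

import pytest

from lanminer.bgc_classify import ClassifierConfig
from lanminer.fixtures import FixtureSpec, build_role_hmms, make_genome, make_training_peptides
from lanminer.pipeline import PipelineConfig
from lanminer.precursor_score import prepare_training_matrix, select_features, train_svm


@pytest.fixture(scope="session")
def role_hmms(tmp_path_factory):
    return build_role_hmms(tmp_path_factory.mktemp("hmms"))


@pytest.fixture(scope="session")
def classifier_config(role_hmms):
    return ClassifierConfig(**{f"{role}_hmm": hmm for role, hmm in role_hmms.items()})


@pytest.fixture(scope="session")
def trained_svm():
    peptides = make_training_peptides(150, 150, separation=4.0, seed=11)
    X, y, _ = prepare_training_matrix(peptides)
    mask = select_features(X, y)
    return train_svm(X, y, mask, lan_class="I")


@pytest.fixture(scope="session")
def svm_per_class(trained_svm):
    return {c: dataclasses.replace(trained_svm, lan_class=c) for c in ("I", "II", "III", "IV")}


@pytest.fixture(scope="session")
def pipeline_config(classifier_config, svm_per_class):
    return PipelineConfig(classifier=classifier_config, models=svm_per_class)


@pytest.fixture(scope="session")
def fixture_genome():
    return make_genome(FixtureSpec(seed=3, classes=("I", "II", "III")))
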