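import pytest
from hypothesis import HealthCheck, settings

from upkmine.chemsim import ChemicalRecord
from upkmine.corpus import EffectLexicon
from upkmine.parsegraph import ParseGraph, ParseLink, ParseToken
from upkmine.recognizer import SemanticLexicon

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_graph(sentence_id, surfaces, links):
    """Helper: graph from surfaces and (left, right, label) triples."""
    return ParseGraph(
        sentence_id=sentence_id,
        tokens=tuple(ParseToken(i, s) for i, s in enumerate(surfaces)),
        links=frozenset(ParseLink(l, r, lab) for l, r, lab in links),
    )


@pytest.fixture
def fig_rule_graph():
    """'tolfenamic acid induces degradation': the canonical rule-creation
    linkage — compound substance, leftward subject link into the effect verb."""
    return make_graph(
        "fig:0",
        ["tolfenamic", "acid", "induces", "degradation"],
        [(0, 1, "AN"), (1, 2, "Ss"), (2, 3, "Os")],
    )


@pytest.fixture
def effect_lexicon():
    return EffectLexicon.default()


@pytest.fixture
def sem_lexicon():
    return SemanticLexicon(
        {
            "fisetin": ("SUBSTANCE", "Organic Chemical"),
            "wogonin": ("SUBSTANCE", "Organic Chemical"),
            "docetaxel": ("SUBSTANCE", "Organic Chemical"),
            "genistein": ("SUBSTANCE", "Organic Chemical"),
            "tolfenamic acid": ("SUBSTANCE", "Pharmacologic Substance"),
            "apoptosis": ("PROCESS", "Cell Function"),
            "Sp protein degradation": ("PROCESS", "Cell Function"),
            "leukemia": ("DISEASE", "Neoplastic Process"),
            "HCT-116 cells": ("BODYPART", "Cell"),
            "cancer cell lines": ("BODYPART", "Cell"),
            "malignant T cells": ("BODYPART", "Cell"),
        }
    )


@pytest.fixture
def wogonin_record():
    return ChemicalRecord(
        name="Wogonin",
        semantic_type="Organic Chemical",
        smiles="COc1c(O)cc2oc(-c3ccccc3)cc(=O)c2c1O",
        formula="C16H12O5",
        xlogp=2.74,
    )


@pytest.fixture
def fisetin_record():
    return ChemicalRecord(
        name="Fisetin",
        semantic_type="Organic Chemical",
        smiles="O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)ccc12",
        formula="C15H10O6",
        xlogp=2.77,
    )


@pytest.fixture
def cordycepin_record():
    return ChemicalRecord(
        name="Cordycepin",
        semantic_type="Pharmacologic Substance",
        smiles="Nc1ncnc2c1ncn2C1OC(CO)CC1O",
        formula="C_10_H_13_N_5_O_3_",
        xlogp=-1.25,
    )


@pytest.fixture
def fludarabine_record():
    return ChemicalRecord(
        name="Fludarabine",
        semantic_type="Pharmacologic Substance",
        smiles="Nc1nc(F)nc2c1ncn2C1OC(CO)C(O)C1O",
        formula="C_10_H_12_FN_5_O_4_",
        xlogp=-1.38,
    )
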