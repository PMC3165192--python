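"""Similarity measure: formulas, SMILES graphs, MCS, comparative values.

The connected-MCS search is validated against an independent brute-force
oracle (enumerate all connected vertex subsets of the smaller molecule and
test each induced subgraph for an isomorphic, compatibility-respecting
embedding in the larger one) and, where subset semantics coincide, against
RDKit.
"""

from itertools import combinations

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from networkx.algorithms.isomorphism import GraphMatcher

from upkmine.chemsim import (
    ChemicalRecord,
    FormulaError,
    MolGraph,
    SmilesError,
    atomic_comparative,
    mcs_size,
    parse_formula,
    parse_smiles,
    semtype_comparative,
    similarity_score,
    structural_comparative,
    tanimoto_mcs,
    xlogp_comparative,
)


class TestParseFormula:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C10H13N5O3", {"C": 10, "H": 13, "N": 5, "O": 3}),
            ("C_10_H_13_N_5_O_3_", {"C": 10, "H": 13, "N": 5, "O": 3}),
            ("C", {"C": 1}),
            ("C16H12O5", {"C": 16, "H": 12, "O": 5}),
            ("C10H12FN5O4", {"C": 10, "H": 12, "F": 1, "N": 5, "O": 4}),
        ],
    )
    def test_counts(self, formula, expected):
        counts = parse_formula(formula)
        assert counts == expected

    @pytest.mark.parametrize("bad", ["", "Xx3", "12C", "C10h"])
    def test_malformed(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)


class TestAtomicComparative:
    def test_purine_nucleosides_similar(self):
        # distance 3/32 ~ 0.094, inside the 0.2 band
        a = parse_formula("C10H13N5O3")
        b = parse_formula("C10H12FN5O4")
        assert atomic_comparative(a, b) == 1

    def test_flavonoids_similar(self):
        # distance 4/33 ~ 0.121
        assert atomic_comparative(parse_formula("C16H12O5"), parse_formula("C15H10O6")) == 1

    def test_grossly_different_not_similar(self):
        # distance 27/31 ~ 0.87
        assert atomic_comparative(parse_formula("CH4"), parse_formula("C10H13N5O3")) == 0


class TestParseSmiles:
    def test_linear_chain(self):
        mol = parse_smiles("CCO")
        assert [a[0] for a in mol.atoms] == ["C", "C", "O"]
        assert mol.bonds == frozenset({(0, 1), (1, 2)})

    def test_aromatic_ring_closure(self):
        mol = parse_smiles("c1ccccc1")
        assert len(mol) == 6
        assert all(elem == "C" and aromatic for elem, aromatic in mol.atoms)
        assert len(mol.bonds) == 6

    def test_branches_and_brackets(self):
        mol = parse_smiles("CC(=O)[O-]")  # acetate
        assert [a[0] for a in mol.atoms] == ["C", "C", "O", "O"]
        assert (1, 2) in mol.bonds and (1, 3) in mol.bonds

    @pytest.mark.parametrize("bad", ["C1CC", "C(C", "CC)", "C%1C", "[Qq]C", ""])
    def test_malformed(self, bad):
        with pytest.raises(SmilesError):
            parse_smiles(bad)

    @pytest.mark.parametrize(
        "smiles",
        ["CCO", "c1ccccc1", "CC(=O)O", "C1CCCCC1", "c1ccncc1", "N#Cc1ccccc1", "ClCCl"],
    )
    def test_heavy_atom_count_matches_rdkit(self, smiles):
        rdkit_chem = pytest.importorskip("rdkit.Chem")
        mol = rdkit_chem.MolFromSmiles(smiles)
        ours = parse_smiles(smiles)
        assert len(ours) == mol.GetNumAtoms()
        assert len(ours.bonds) == mol.GetNumBonds()


# --- MCS ------------------------------------------------------------------

FIXTURE_SMILES = [
    "CCO",          # ethanol
    "CCCO",         # propanol
    "CC(=O)O",      # acetic acid
    "c1ccccc1",     # benzene
    "c1ccncc1",     # pyridine
    "Cc1ccccc1",    # toluene
    "C1CCCCC1",     # cyclohexane
    "NCCO",         # ethanolamine
    "CC(N)C(=O)O",  # alanine
    "OCC1OCCC1O",   # tetrahydrofuran diol (ring + tail)
]


def to_nx(mol: MolGraph) -> nx.Graph:
    g = nx.Graph()
    for i, atom in enumerate(mol.atoms):
        g.add_node(i, atom=atom)
    g.add_edges_from(mol.bonds)
    return g


def brute_force_mcs(a: MolGraph, b: MolGraph) -> int:
    """Oracle: largest connected induced common subgraph by exhaustive
    enumeration over the smaller molecule's vertex subsets."""
    if len(a) > len(b):
        a, b = b, a
    ga, gb = to_nx(a), to_nx(b)
    same_atom = lambda n1, n2: n1["atom"] == n2["atom"]
    for size in range(len(a), 0, -1):
        for subset in combinations(range(len(a)), size):
            sub = ga.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            matcher = GraphMatcher(gb, sub, node_match=same_atom)
            if matcher.subgraph_is_isomorphic():
                return size
    return 0


class TestMCS:
    @pytest.mark.parametrize("smiles", FIXTURE_SMILES)
    def test_identity(self, smiles):
        mol = parse_smiles(smiles)
        assert mcs_size(mol, mol) == len(mol)

    def test_chain_extension(self):
        assert mcs_size(parse_smiles("CCO"), parse_smiles("CCCO")) == 3

    def test_incompatible_atoms(self):
        assert mcs_size(parse_smiles("C"), parse_smiles("N")) == 0

    def test_benzene_vs_pyridine(self):
        # five shared aromatic carbons form the largest connected overlap
        assert mcs_size(parse_smiles("c1ccccc1"), parse_smiles("c1ccncc1")) == 5

    def test_aromaticity_must_agree(self):
        # benzene vs cyclohexane: aromatic vs aliphatic carbons never match
        assert mcs_size(parse_smiles("c1ccccc1"), parse_smiles("C1CCCCC1")) == 0

    @pytest.mark.parametrize(
        "left,right",
        list(combinations(range(len(FIXTURE_SMILES)), 2)),
        ids=lambda i: FIXTURE_SMILES[i] if isinstance(i, int) else i,
    )
    def test_equals_brute_force_oracle(self, left, right):
        a, b = parse_smiles(FIXTURE_SMILES[left]), parse_smiles(FIXTURE_SMILES[right])
        assert mcs_size(a, b) == brute_force_mcs(a, b)


class TestTanimoto:
    def test_identical_molecule(self):
        mol = parse_smiles("CC(=O)O")
        sim = tanimoto_mcs(mol, mol)
        assert sim.tanimoto == 1.0
        assert sim.substructure

    def test_chain_extension_value(self):
        sim = tanimoto_mcs(parse_smiles("CCO"), parse_smiles("CCCO"))
        assert sim.tanimoto == pytest.approx(0.75)
        assert sim.substructure

    def test_benzene_pyridine_value(self):
        sim = tanimoto_mcs(parse_smiles("c1ccccc1"), parse_smiles("c1ccncc1"))
        assert sim.tanimoto == pytest.approx(5 / 7)
        assert not sim.substructure

    @pytest.mark.parametrize(
        "left,right", list(combinations(FIXTURE_SMILES[:6], 2))
    )
    def test_bounds_and_symmetry(self, left, right):
        a, b = parse_smiles(left), parse_smiles(right)
        ab, ba = tanimoto_mcs(a, b), tanimoto_mcs(b, a)
        assert 0.0 <= ab.tanimoto <= 1.0
        assert ab.tanimoto == pytest.approx(ba.tanimoto)


class TestComparatives:
    @pytest.mark.parametrize(
        "t,sub,value",
        [(0.9, False, 1), (0.75, False, 1), (0.4, True, 0.5), (0.4, False, 0), (1.0, True, 1)],
    )
    def test_structural(self, t, sub, value):
        assert structural_comparative(t, sub) == value

    @pytest.mark.parametrize(
        "x1,x2,value",
        [
            (-1.25, -1.38, 1),
            (2.74, 2.77, 1),
            (0.0, 0.7, 0.5),
            (0.0, 1.5, 0),
            (0.0, 0.5, 1),   # boundary: diff exactly 0.5 is Similar
            (0.0, 1.0, 0),   # boundary: diff exactly 1.0 is Not Similar
        ],
    )
    def test_xlogp_bands(self, x1, x2, value):
        assert xlogp_comparative(x1, x2) == value

    @pytest.mark.parametrize(
        "t1,t2,value",
        [
            ("Pharmacologic Substance", "Pharmacologic Substance", 1),
            ("Organic Chemical", "Pharmacologic Substance", 0),
            ("", "Organic Chemical", 0),
            ("organic chemical", "Organic Chemical", 1),
        ],
    )
    def test_semtype(self, t1, t2, value):
        assert semtype_comparative(t1, t2) == value


class TestSimilarityScore:
    def test_purine_nucleoside_pair_scores_four(self, cordycepin_record, fludarabine_record):
        breakdown = similarity_score(cordycepin_record, fludarabine_record, structural_t=0.9)
        assert (
            breakdown.semtype_value,
            breakdown.structural_value,
            breakdown.atomic_value,
            breakdown.xlogp_value,
        ) == (1, 1, 1, 1)
        assert breakdown.total == 4

    def test_flavonoid_pair_scores_four(self, wogonin_record, fisetin_record):
        assert similarity_score(wogonin_record, fisetin_record, structural_t=0.75).total == 4

    def test_everything_different_scores_zero(self):
        a = ChemicalRecord("a", "Organic Chemical", "CCCCCCCC", "C8H18", 5.2)
        b = ChemicalRecord("b", "Hormone", "[Na+].[Cl-]", "NaCl", -3.0)
        assert similarity_score(a, b).total == 0

    def test_symmetry(self, wogonin_record, fisetin_record):
        ab = similarity_score(wogonin_record, fisetin_record)
        ba = similarity_score(fisetin_record, wogonin_record)
        assert ab == ba

    def test_self_score_is_four(self, cordycepin_record):
        assert similarity_score(cordycepin_record, cordycepin_record).total == 4

    def test_missing_fields_degrade_not_fail(self):
        a = ChemicalRecord("a", "Organic Chemical", "", "", None)
        b = ChemicalRecord("b", "Organic Chemical", "CCO", "C2H6O", 0.1)
        breakdown = similarity_score(a, b)
        assert breakdown.total == 1  # only the semantic type comparable

    @given(
        st.tuples(
            st.sampled_from(["Organic Chemical", "Pharmacologic Substance"]),
            st.sampled_from(FIXTURE_SMILES[:6]),
            st.sampled_from(["C2H6O", "C6H6", "C7H8", "C3H8O"]),
            st.floats(min_value=-4, max_value=4, allow_nan=False),
        ),
        st.tuples(
            st.sampled_from(["Organic Chemical", "Pharmacologic Substance"]),
            st.sampled_from(FIXTURE_SMILES[:6]),
            st.sampled_from(["C2H6O", "C6H6", "C7H8", "C3H8O"]),
            st.floats(min_value=-4, max_value=4, allow_nan=False),
        ),
    )
    @settings(max_examples=40)
    def test_score_quantized_and_bounded(self, attrs_a, attrs_b):
        a = ChemicalRecord("a", *attrs_a)
        b = ChemicalRecord("b", *attrs_b)
        total = similarity_score(a, b).total
        assert 0.0 <= total <= 4.0
        assert (total * 2) == int(total * 2)  # multiples of 0.5
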