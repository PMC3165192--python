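"""Four-component substance similarity.

Two substances are compared on four attributes, each mapped to a comparative
value and summed:

======================  ==========================================  =========
component               rule (defaults)                             values
======================  ==========================================  =========
semantic type           equal (case-insensitive) type strings       0 / 1
structure               MCS-Tanimoto t >= 0.75 -> 1; common sub-    0 / 0.5 / 1
                        structure covering the smaller molecule
                        -> 0.5
atomic count            relative Manhattan distance between         0 / 1
                        element counts <= 0.2
XLogP                   |difference| <= 0.5 -> 1; < 1 -> 0.5        0 / 0.5 / 1
======================  ==========================================  =========

The aggregate score lies in [0, 4] on a 0.5 grid; 4 means the substances are
interchangeable for hypothesis purposes and the default hypothesis threshold
is 2. Structural similarity is the MCS-Tanimoto m / (|A| + |B| - m) with m
the size of a maximum common connected subgraph over heavy atoms (element
and aromaticity must agree; bond orders are ignored), found by backtracking
search.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

from .config import Thresholds, DEFAULT_THRESHOLDS

__all__ = [
    "ChemicalRecord",
    "MolGraph",
    "SimilarityBreakdown",
    "MCSResult",
    "StructuralSimilarity",
    "FormulaError",
    "SmilesError",
    "parse_formula",
    "atomic_comparative",
    "parse_smiles",
    "mcs",
    "mcs_size",
    "tanimoto_mcs",
    "structural_comparative",
    "xlogp_comparative",
    "semtype_comparative",
    "similarity_score",
    "read_chem_table",
    "write_chem_table",
]

logger = logging.getLogger(__name__)


class FormulaError(ValueError):
    """Molecular formula does not parse."""


class SmilesError(ValueError):
    """SMILES string outside the supported subset or ill-formed."""


# ---------------------------------------------------------------------------
# Molecular formulas
# ---------------------------------------------------------------------------

_ELEMENTS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U""".split()
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)_?(\d*)_?")


def parse_formula(formula: str) -> dict[str, int]:
    """Element counts from Hill-style notation.

    Accepts plain ("C10H13N5O3") and underscore-subscript
    ("C_10_H_13_N_5_O_3_") forms. Unknown element symbols and stray
    characters raise :class:`FormulaError`.
    """
    counts: dict[str, int] = {}
    pos = 0
    text = formula.strip()
    if not text:
        raise FormulaError("empty formula")
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or m.end() == pos:
            raise FormulaError(f"{formula!r}: cannot parse at position {pos}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in _ELEMENTS:
            raise FormulaError(f"{formula!r}: unknown element {symbol!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return counts


def atomic_comparative(
    a: Mapping[str, int],
    b: Mapping[str, int],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> float:
    """1 when the element compositions are close, else 0.

    Distance is the Manhattan distance between element-count vectors divided
    by the larger total atom count; "similar" means distance <= 0.2.
    """
    total_a, total_b = sum(a.values()), sum(b.values())
    if total_a == 0 or total_b == 0:
        return 0.0
    diff = sum(abs(a.get(e, 0) - b.get(e, 0)) for e in set(a) | set(b))
    return 1.0 if diff / max(total_a, total_b) <= thresholds.atomic_rel_dist else 0.0


# ---------------------------------------------------------------------------
# SMILES subset parser -> heavy-atom graph
# ---------------------------------------------------------------------------

_ORGANIC_TWO = ("Cl", "Br")
_ORGANIC_ONE = frozenset("BCNOPSFI")
_AROMATIC_ORGANIC = frozenset("bcnops")
_BOND_CHARS = frozenset("-=#$:/\\")
_BRACKET_RE = re.compile(r"^(\d+)?([A-Za-z][a-z]?)")


@dataclass(frozen=True)
class MolGraph:
    """Heavy-atom graph: (element, aromatic) atoms plus unordered bonds."""

    atoms: tuple[tuple[str, bool], ...]
    bonds: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < j < n):
                raise ValueError(f"invalid bond ({i},{j}) for {n} atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.atoms]
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj


def parse_smiles(smiles: str) -> MolGraph:
    """Heavy-atom graph from a SMILES subset.

    Supported: organic-subset atoms, aromatic lowercase, bracket atoms
    (isotope/stereo/H-count/charge ignored; explicit [H] atoms are skipped),
    branches, ring closures (``1``–``9`` and ``%nn``), bond symbols and the
    dot disconnector. Unmatched parentheses or ring closures raise
    :class:`SmilesError` with the offending position.
    """
    atoms: list[tuple[str, bool]] = []
    bonds: set[tuple[int, int]] = set()
    stack: list[int | None] = []
    ring_open: dict[str, int] = {}
    prev: int | None = None
    pos = 0
    text = smiles.strip()
    if not text:
        raise SmilesError("empty SMILES")

    def add_atom(element: str, aromatic: bool) -> None:
        nonlocal prev
        atoms.append((element, aromatic))
        idx = len(atoms) - 1
        if prev is not None:
            bonds.add((min(prev, idx), max(prev, idx)))
        prev = idx

    def close_ring(token: str, at: int) -> None:
        if token in ring_open:
            other = ring_open.pop(token)
            if prev is None or other == prev:
                raise SmilesError(f"position {at}: bad ring closure {token}")
            bonds.add((min(prev, other), max(prev, other)))
        else:
            if prev is None:
                raise SmilesError(f"position {at}: ring digit before any atom")
            ring_open[token] = prev

    while pos < len(text):
        c = text[pos]
        if c in _BOND_CHARS:
            pos += 1  # connectivity only; bond orders/stereo not recorded
        elif c == ".":
            prev = None
            pos += 1
        elif c == "(":
            if prev is None:
                raise SmilesError(f"position {pos}: branch before any atom")
            stack.append(prev)
            pos += 1
        elif c == ")":
            if not stack:
                raise SmilesError(f"position {pos}: unmatched ')'")
            prev = stack.pop()
            pos += 1
        elif c == "%":
            if pos + 2 >= len(text) or not text[pos + 1 : pos + 3].isdigit():
                raise SmilesError(f"position {pos}: bad %nn ring closure")
            close_ring(text[pos + 1 : pos + 3], pos)
            pos += 3
        elif c.isdigit():
            close_ring(c, pos)
            pos += 1
        elif c == "[":
            end = text.find("]", pos)
            if end < 0:
                raise SmilesError(f"position {pos}: unclosed bracket atom")
            body = text[pos + 1 : end]
            m = _BRACKET_RE.match(body)
            if not m:
                raise SmilesError(f"position {pos}: cannot read bracket atom {body!r}")
            symbol = m.group(2)
            aromatic = symbol[0].islower()
            element = symbol.capitalize()
            if element == "H":
                # explicit hydrogen: not a heavy atom; drop it and its bond
                pos = end + 1
                continue
            if element not in _ELEMENTS:
                raise SmilesError(f"position {pos}: unknown element {symbol!r}")
            add_atom(element, aromatic)
            pos = end + 1
        elif text[pos : pos + 2] in _ORGANIC_TWO:
            add_atom(text[pos : pos + 2], False)
            pos += 2
        elif c in _ORGANIC_ONE:
            add_atom(c, False)
            pos += 1
        elif c in _AROMATIC_ORGANIC:
            add_atom(c.upper(), True)
            pos += 1
        else:
            raise SmilesError(f"position {pos}: unexpected character {c!r}")
    if stack:
        raise SmilesError("unmatched '(' at end of SMILES")
    if ring_open:
        digits = ", ".join(sorted(ring_open))
        raise SmilesError(f"unclosed ring closure(s): {digits}")
    return MolGraph(atoms=tuple(atoms), bonds=frozenset(bonds))


# ---------------------------------------------------------------------------
# Maximum common connected subgraph (McGregor-style backtracking)
# ---------------------------------------------------------------------------


class MCSResult(NamedTuple):
    size: int
    exact: bool  # False when the search budget capped the result (lower bound)


def _compatible(a: MolGraph, b: MolGraph, i: int, j: int) -> bool:
    return a.atoms[i] == b.atoms[j]  # same element, same aromaticity


def mcs(
    a: MolGraph,
    b: MolGraph,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> MCSResult:
    """Size of a maximum common connected induced subgraph.

    Atoms match on (element, aromatic flag); adjacency must agree in both
    molecules (bond orders ignored). Exact for inputs within the configured
    atom budget; beyond it the search is capped and the result is a lower
    bound flagged ``exact=False``.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("MCS requires non-empty molecules")
    if len(a) > len(b):
        a, b = b, a
    adj_a, adj_b = a.adjacency(), b.adjacency()
    n_a, n_b = len(a), len(b)
    budget_ok = max(n_a, n_b) <= thresholds.mcs_atom_budget
    # node-expansion cap keeps worst cases bounded; generous for small inputs
    limit = 2_000_000 if budget_ok else 200_000
    expansions = 0
    best = 0
    capped = False

    def extend(
        mapping: dict[int, int], used_b: set[int], excluded: set[int], seed: int
    ) -> None:
        """Branch on the smallest frontier atom: map it or exclude it."""
        nonlocal best, expansions, capped
        expansions += 1
        if expansions > limit:
            capped = True
            return
        best = max(best, len(mapping))
        eligible = [
            i
            for i in range(seed + 1, n_a)
            if i not in mapping and i not in excluded
        ]
        upper = len(mapping) + min(len(eligible), n_b - len(used_b))
        if upper <= best:
            return
        frontier = [i for i in eligible if adj_a[i] & mapping.keys()]
        if not frontier:
            return
        i = frontier[0]
        for j in range(n_b):
            if j in used_b or not _compatible(a, b, i, j):
                continue
            if any((u in adj_a[i]) != (v in adj_b[j]) for u, v in mapping.items()):
                continue
            mapping[i] = j
            used_b.add(j)
            extend(mapping, used_b, excluded, seed)
            del mapping[i]
            used_b.discard(j)
            if capped:
                return
        excluded.add(i)
        extend(mapping, used_b, excluded, seed)
        excluded.discard(i)

    for seed in range(n_a):
        if n_a - seed <= best:
            break
        for j in range(n_b):
            if _compatible(a, b, seed, j):
                extend({seed: j}, {j}, set(), seed)
                if capped:
                    break
        if capped:
            break
    if capped:
        logger.warning(
            "MCS search capped (budget %d atoms); returning lower bound %d",
            thresholds.mcs_atom_budget, best,
        )
    return MCSResult(size=best, exact=not capped)


def mcs_size(a: MolGraph, b: MolGraph, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> int:
    return mcs(a, b, thresholds).size


class StructuralSimilarity(NamedTuple):
    tanimoto: float
    substructure: bool
    mcs_size: int
    exact: bool


def tanimoto_mcs(
    a: MolGraph, b: MolGraph, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> StructuralSimilarity:
    """MCS-Tanimoto t = m / (|a| + |b| - m); substructure when the common
    subgraph covers the smaller molecule entirely."""
    result = mcs(a, b, thresholds)
    m = result.size
    t = m / (len(a) + len(b) - m)
    return StructuralSimilarity(
        tanimoto=t,
        substructure=m == min(len(a), len(b)),
        mcs_size=m,
        exact=result.exact,
    )


# ---------------------------------------------------------------------------
# Comparative values and the aggregate score
# ---------------------------------------------------------------------------


def structural_comparative(
    t: float, substructure: bool, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> float:
    """1 = similar (t >= 0.75); 0.5 = substructure; 0 otherwise."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"similarity {t} outside [0, 1]")
    if t >= thresholds.structural_similar:
        return 1.0
    return 0.5 if substructure else 0.0


def xlogp_comparative(
    x1: float, x2: float, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> float:
    """1 when |x1-x2| <= 0.5; 0.5 in the (0.5, 1) band; 0 at >= 1."""
    if not (math.isfinite(x1) and math.isfinite(x2)):
        raise ValueError("XLogP values must be finite")
    d = abs(x1 - x2)
    if d <= thresholds.xlogp_similar:
        return 1.0
    if d < thresholds.xlogp_somewhat:
        return 0.5
    return 0.0


def semtype_comparative(t1: str, t2: str) -> float:
    """1 iff both semantic types are non-empty and equal, case-insensitively."""
    if not t1.strip() or not t2.strip():
        return 0.0
    return 1.0 if t1.strip().casefold() == t2.strip().casefold() else 0.0


@dataclass(frozen=True)
class ChemicalRecord:
    """A substance's comparison attributes (local stand-in for a chemical DB)."""

    name: str
    semantic_type: str = ""
    smiles: str = ""
    formula: str = ""
    xlogp: float | None = None


@dataclass(frozen=True)
class SimilarityBreakdown:
    semtype_value: float
    structural_value: float
    atomic_value: float
    xlogp_value: float

    def __post_init__(self) -> None:
        for value in (self.semtype_value, self.atomic_value):
            if value not in (0.0, 1.0):
                raise ValueError("semantic-type and atomic components are binary")
        for value in (self.structural_value, self.xlogp_value):
            if value not in (0.0, 0.5, 1.0):
                raise ValueError("components take values in {0, 0.5, 1}")

    @property
    def total(self) -> float:
        return (
            self.semtype_value
            + self.structural_value
            + self.atomic_value
            + self.xlogp_value
        )


def similarity_score(
    a: ChemicalRecord,
    b: ChemicalRecord,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    structural_t: float | None = None,
    substructure: bool = False,
) -> SimilarityBreakdown:
    """Four comparative components and their sum, symmetric in a and b.

    ``structural_t`` feeds an externally computed structural similarity (e.g.
    a published SMSD value) straight into the comparative table, bypassing the
    internal MCS; otherwise both SMILES are parsed and compared. A missing or
    unparsable attribute degrades that component to 0 with a warning rather
    than failing the pair.
    """
    semtype_value = semtype_comparative(a.semantic_type, b.semantic_type)

    structural_value = 0.0
    if structural_t is not None:
        structural_value = structural_comparative(structural_t, substructure, thresholds)
    elif a.smiles and b.smiles:
        try:
            sim = tanimoto_mcs(parse_smiles(a.smiles), parse_smiles(b.smiles), thresholds)
            structural_value = structural_comparative(
                sim.tanimoto, sim.substructure, thresholds
            )
        except (SmilesError, ValueError) as exc:
            logger.warning("structural comparison failed for %s/%s: %s", a.name, b.name, exc)
    else:
        logger.warning("missing SMILES for %s/%s; structural component 0", a.name, b.name)

    atomic_value = 0.0
    if a.formula and b.formula:
        try:
            atomic_value = atomic_comparative(
                parse_formula(a.formula), parse_formula(b.formula), thresholds
            )
        except FormulaError as exc:
            logger.warning("atomic comparison failed for %s/%s: %s", a.name, b.name, exc)
    else:
        logger.warning("missing formula for %s/%s; atomic component 0", a.name, b.name)

    xlogp_value = 0.0
    if a.xlogp is not None and b.xlogp is not None:
        xlogp_value = xlogp_comparative(a.xlogp, b.xlogp, thresholds)
    else:
        logger.warning("missing XLogP for %s/%s; component 0", a.name, b.name)

    return SimilarityBreakdown(
        semtype_value=semtype_value,
        structural_value=structural_value,
        atomic_value=atomic_value,
        xlogp_value=xlogp_value,
    )


# ---------------------------------------------------------------------------
# Chemical records table
# ---------------------------------------------------------------------------

CHEM_COLUMNS = ("name", "semantic_type", "smiles", "formula", "xlogp")


def _norm_name(name: str) -> str:
    return re.sub(r"\s+", " ", name).strip().casefold()


def read_chem_table(path: str | Path) -> dict[str, ChemicalRecord]:
    """Records keyed by whitespace-normalized, case-folded name."""
    table: dict[str, ChemicalRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != CHEM_COLUMNS:
            raise ValueError(f"{path}: expected header {' '.join(CHEM_COLUMNS)}")
        for row in reader:
            if not row:
                continue
            name, semtype, smiles, formula, xlogp = row
            key = _norm_name(name)
            if key in table:
                raise ValueError(f"{path}: duplicate substance name {name!r}")
            table[key] = ChemicalRecord(
                name=name,
                semantic_type=semtype,
                smiles=smiles,
                formula=formula,
                xlogp=float(xlogp) if xlogp not in ("", "N/A") else None,
            )
    return table


def write_chem_table(
    records: Iterable[ChemicalRecord], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CHEM_COLUMNS)
        for rec in sorted(records, key=lambda r: _norm_name(r.name)):
            writer.writerow(
                (
                    rec.name,
                    rec.semantic_type,
                    rec.smiles,
                    rec.formula,
                    "" if rec.xlogp is None else repr(rec.xlogp),
                )
            )
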