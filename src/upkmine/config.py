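"""Tunable thresholds and their config-file loader.

All calibrated constants of the pipeline live here: the comparative-value
cutoffs of the similarity measure, the hypothesis score threshold, the
entity-expansion link set, and the MCS search budget. A plain ``key=value``
file (``#`` comments) can override any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

__all__ = ["Thresholds", "DEFAULT_THRESHOLDS", "load_config"]


@dataclass(frozen=True)
class Thresholds:
    #: MCS-Tanimoto at or above which structures count as Similar (value 1).
    structural_similar: float = 0.75
    #: Relative Manhattan distance between element counts at or below which
    #: atomic composition counts as Similar.
    atomic_rel_dist: float = 0.2
    #: |XLogP difference| at or below which hydrophobicity counts as Similar.
    xlogp_similar: float = 0.5
    #: Upper edge (exclusive) of the Somewhat-similar XLogP band (value 0.5);
    #: differences at or beyond it score 0.
    xlogp_somewhat: float = 1.0
    #: Minimum pair-similarity total for a hypothesis to survive (max is 4).
    score_threshold: float = 2.0
    #: Reduced link labels followed leftward when expanding entity names.
    expansion_links: tuple[str, ...] = ("AN", "A", "G")
    #: Heavy-atom count above which the exact MCS search is capped.
    mcs_atom_budget: int = 40


DEFAULT_THRESHOLDS = Thresholds()

_FLOAT_KEYS = {
    "structural_similar",
    "atomic_rel_dist",
    "xlogp_similar",
    "xlogp_somewhat",
    "score_threshold",
}


def load_config(path: str | Path) -> Thresholds:
    """Thresholds from a ``key=value`` file; unknown keys are an error."""
    known = {f.name for f in fields(Thresholds)}
    overrides: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in _FLOAT_KEYS:
            overrides[key] = float(value)
        elif key == "mcs_atom_budget":
            overrides[key] = int(value)
        elif key == "expansion_links":
            overrides[key] = tuple(part.strip() for part in value.split(",") if part.strip())
    return replace(DEFAULT_THRESHOLDS, **overrides)
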