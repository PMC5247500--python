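"""Readers and writers for discrete character matrices and tree files.

NEXUS (datatype=standard) goes through dendropy; relaxed PHYLIP and TNT
xread are simple whitespace formats written directly. All functions work on
strings; callers handle files.
"""

from __future__ import annotations

import numpy as np
import dendropy
from dendropy.datamodel.charstatemodel import StateAlphabet

from .simulate import CharacterMatrix
from .trees import Tree

__all__ = [
    "write_nexus",
    "read_nexus",
    "write_phylip",
    "read_phylip",
    "write_tnt",
    "read_matrix",
    "write_trees",
    "read_trees",
]

_MISSING = "?"


def _row_string(states: np.ndarray) -> str:
    return "".join(_MISSING if s < 0 else str(int(s)) for s in states)


def _matrix_from_rows(taxa: list[str], rows: list[str]) -> CharacterMatrix:
    n_chars = len(rows[0])
    if any(len(r) != n_chars for r in rows):
        raise ValueError("ragged character matrix")
    states = np.empty((len(taxa), n_chars), dtype=np.int8)
    for i, r in enumerate(rows):
        for j, ch in enumerate(r):
            if ch in ("?", "-"):
                states[i, j] = -1
            elif ch in "0123":
                states[i, j] = int(ch)
            else:
                raise ValueError(f"unsupported state symbol {ch!r}")
    # characters whose observed states stay within {0,1} are treated binary
    is_binary = np.array(
        [states[:, j][states[:, j] >= 0].max(initial=0) <= 1 for j in range(n_chars)]
    )
    return CharacterMatrix(list(taxa), states, is_binary)


def write_nexus(matrix: CharacterMatrix) -> str:
    sa = StateAlphabet(fundamental_states="0123", no_data_symbol="?")
    d = {t: _row_string(matrix.states[i]) for i, t in enumerate(matrix.taxa)}
    cm = dendropy.StandardCharacterMatrix.from_dict(d, default_state_alphabet=sa)
    return cm.as_string(schema="nexus")


def read_nexus(text: str) -> CharacterMatrix:
    cm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    taxa = [t.label for t in cm.taxon_namespace]
    rows = [str(cm[t]).replace(" ", "") for t in cm.taxon_namespace]
    return _matrix_from_rows(taxa, rows)


def write_phylip(matrix: CharacterMatrix) -> str:
    """Relaxed PHYLIP: header then `name<whitespace>states` per line."""
    lines = [f"{matrix.n_taxa} {matrix.n_characters}"]
    width = max(len(t) for t in matrix.taxa) + 2
    for i, t in enumerate(matrix.taxa):
        lines.append(f"{t:<{width}}{_row_string(matrix.states[i])}")
    return "\n".join(lines) + "\n"


def read_phylip(text: str) -> CharacterMatrix:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    try:
        n_taxa, n_chars = (int(x) for x in lines[0].split()[:2])
    except (ValueError, IndexError) as exc:
        raise ValueError("bad phylip header") from exc
    taxa, rows = [], []
    for ln in lines[1 : 1 + n_taxa]:
        name, seq = ln.split(None, 1)
        taxa.append(name)
        rows.append(seq.replace(" ", ""))
    if len(taxa) != n_taxa or any(len(r) != n_chars for r in rows):
        raise ValueError("phylip dimensions do not match header")
    return _matrix_from_rows(taxa, rows)


def write_tnt(matrix: CharacterMatrix) -> str:
    """TNT ``xread`` block (states only; no character annotations)."""
    lines = [
        "xread",
        f"'{matrix.n_characters} characters, {matrix.n_taxa} taxa'",
        f"{matrix.n_characters} {matrix.n_taxa}",
    ]
    for i, t in enumerate(matrix.taxa):
        lines.append(f"{t} {_row_string(matrix.states[i])}")
    lines.append(";")
    return "\n".join(lines) + "\n"


def read_matrix(text: str) -> CharacterMatrix:
    """Sniff NEXUS vs relaxed PHYLIP and parse accordingly."""
    if text.lstrip().lower().startswith("#nexus"):
        return read_nexus(text)
    return read_phylip(text)


def write_trees(trees, include_lengths: bool = True) -> str:
    """One newick string per line (.nwk / .trees style)."""
    if isinstance(trees, Tree):
        trees = [trees]
    return "\n".join(t.to_newick(include_lengths=include_lengths) for t in trees) + "\n"


def read_trees(text: str) -> list[Tree]:
    return [
        Tree.from_newick(line)
        for line in text.strip().splitlines()
        if line.strip()
    ]
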