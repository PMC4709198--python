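"""A small, deterministic atom-selection language.

Grammar (case-sensitive keywords, whitespace-separated)::

    expr     := or_expr
    or_expr  := and_expr ( "or" and_expr )*
    and_expr := not_expr ( "and" not_expr )*
    not_expr := "not" not_expr | "(" expr ")" | term
    term     := "all"
              | "role:"    {protein|lipid|ligand|ion|solvent}
              | "chain:"   <chain id>
              | "resid:"   <n> | <n>-<m>          (inclusive range)
              | "resname:" <residue name>
              | "name:"    <atom-name glob>        (fnmatch, e.g. C1*)
              | "element:" <symbol>
              | "region:"  <region label>          (expands via region_map)

Resolution against a :class:`~amphitraj.core.Topology` yields a sorted,
reproducible 0-based index array.
"""

from __future__ import annotations

import fnmatch
import re

import numpy as np

from .core import Topology

__all__ = ["Selection", "resolve", "SelectionError"]


class SelectionError(ValueError):
    pass


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


class Selection:
    """A parsed selection expression; resolve with :func:`resolve`."""

    def __init__(self, expression: str):
        self.expression = expression
        self._ast = _parse(expression)

    def __repr__(self):
        return f"Selection({self.expression!r})"

    def mask(self, topology: Topology) -> np.ndarray:
        """Boolean mask over topology atoms."""
        return _evaluate(self._ast, topology)

    def indices(self, topology: Topology) -> np.ndarray:
        return np.flatnonzero(self.mask(topology))


def resolve(selection: Selection | str, topology: Topology) -> np.ndarray:
    """Resolve a selection (object or expression string) to sorted atom indices."""
    if isinstance(selection, str):
        selection = Selection(selection)
    return selection.indices(topology)


# --- parsing -------------------------------------------------------------

def _parse(expression: str):
    tokens = _TOKEN.findall(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    pos = [0]

    def peek():
        return tokens[pos[0]] if pos[0] < len(tokens) else None

    def take():
        tok = peek()
        pos[0] += 1
        return tok

    def parse_or():
        node = parse_and()
        while peek() == "or":
            take()
            node = ("or", node, parse_and())
        return node

    def parse_and():
        node = parse_not()
        while peek() == "and":
            take()
            node = ("and", node, parse_not())
        return node

    def parse_not():
        tok = peek()
        if tok == "not":
            take()
            return ("not", parse_not())
        if tok == "(":
            take()
            node = parse_or()
            if take() != ")":
                raise SelectionError(f"unbalanced parentheses in {expression!r}")
            return node
        if tok is None or tok in (")", "and", "or"):
            raise SelectionError(f"unexpected token {tok!r} in {expression!r}")
        return ("term", take())

    node = parse_or()
    if peek() is not None:
        raise SelectionError(f"trailing tokens after expression in {expression!r}")
    return node


# --- evaluation ----------------------------------------------------------

def _evaluate(node, top: Topology) -> np.ndarray:
    kind = node[0]
    if kind == "or":
        return _evaluate(node[1], top) | _evaluate(node[2], top)
    if kind == "and":
        return _evaluate(node[1], top) & _evaluate(node[2], top)
    if kind == "not":
        return ~_evaluate(node[1], top)
    return _term_mask(node[1], top)


def _term_mask(term: str, top: Topology) -> np.ndarray:
    if term == "all":
        return np.ones(top.n_atoms, dtype=bool)
    if ":" not in term:
        raise SelectionError(f"malformed term {term!r} (expected key:value or 'all')")
    key, _, value = term.partition(":")
    if key == "role":
        return top.roles == value
    if key == "chain":
        return top.chain_ids == value
    if key == "resname":
        return top.residue_names == value
    if key == "element":
        return np.array([e.upper() == value.upper() for e in top.elements])
    if key == "name":
        return np.array([fnmatch.fnmatchcase(n, value) for n in top.names])
    if key == "resid":
        if "-" in value.lstrip("-")[1:] or (value.count("-") == 1 and not value.startswith("-")):
            lo_s, _, hi_s = value.partition("-")
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(value)
        return (top.residue_ids >= lo) & (top.residue_ids <= hi)
    if key == "region":
        if value not in top.region_map:
            raise SelectionError(
                f"unknown region {value!r}; known regions: {sorted(top.region_map)}"
            )
        members = top.region_map[value]
        return np.array(
            [(c, r) in members for c, r in zip(top.chain_ids, top.residue_ids)],
            dtype=bool,
        )
    raise SelectionError(f"unknown selection key {key!r} in term {term!r}")
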