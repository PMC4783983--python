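"""A small atom-selection language.

Grammar (case-insensitive keywords)::

    expr      := term ("or" term)*
    term      := factor ("and" factor)*
    factor    := "not" factor | "(" expr ")" | primitive
    primitive := "name" NAME+          # one or more atom names
               | "resid" RANGE+       # 0-based residue indices, N or N-M
               | "mainchain" | "sidechain"
               | "solute" | "solvent"
               | "hydrogen" | "heavy"
               | "all"

Selections always return ascending, duplicate-free atom indices, so
``|A and B| + |A or B| = |A| + |B|`` holds for any expressions A, B.
An empty result is legal and produces a warning, not an error.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import SelectionError
from .model import System

_KEYWORDS = {
    "name", "resid", "mainchain", "sidechain", "solute", "solvent",
    "hydrogen", "heavy", "all", "and", "or", "not", "(", ")",
}


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: list[str], system: System):
        self.tokens = tokens
        self.pos = 0
        self.system = system

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    # expr := term (or term)*
    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.take()
        low = tok.lower()
        if low == "not":
            return ~self.factor()
        if tok == "(":
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primitive(low)

    def primitive(self, keyword: str) -> np.ndarray:
        sysm = self.system
        n = sysm.n_atoms
        if keyword == "all":
            return np.ones(n, dtype=bool)
        if keyword == "mainchain":
            return sysm.is_mainchain.copy()
        if keyword == "sidechain":
            return sysm.is_solute & ~sysm.is_mainchain
        if keyword == "solute":
            return sysm.is_solute.copy()
        if keyword == "solvent":
            return ~sysm.is_solute
        if keyword == "hydrogen":
            return sysm.is_hydrogen.copy()
        if keyword == "heavy":
            return ~sysm.is_hydrogen
        if keyword == "name":
            names = self._take_arguments("name")
            wanted = {w.upper() for w in names}
            return np.array([a.name.upper() in wanted for a in sysm.atoms])
        if keyword == "resid":
            ranges = self._take_arguments("resid")
            mask = np.zeros(n, dtype=bool)
            resid = sysm.residue_indices
            for r in ranges:
                if "-" in r[1:]:  # allow negative-free N-M ranges
                    lo_s, hi_s = r.split("-", 1)
                    lo, hi = int(lo_s), int(hi_s)
                else:
                    lo = hi = int(r)
                mask |= (resid >= lo) & (resid <= hi)
            return mask
        raise SelectionError(f"unknown selection keyword {keyword!r}")

    def _take_arguments(self, keyword: str) -> list[str]:
        args: list[str] = []
        while self.peek() is not None and self.peek().lower() not in _KEYWORDS:
            args.append(self.take())
        if not args:
            raise SelectionError(f"'{keyword}' requires at least one argument")
        return args


def select_atoms(system: System, expression: str) -> np.ndarray:
    """Evaluate a selection expression; returns ascending atom indices."""
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    parser = _Parser(tokens, system)
    mask = parser.expr()
    if parser.peek() is not None:
        raise SelectionError(f"trailing tokens near {parser.peek()!r}")
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        warnings.warn(
            f"selection {expression!r} matched no atoms", stacklevel=2
        )
    return indices
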