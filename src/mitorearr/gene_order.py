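"""Signed circular gene-order algebra.

A gene order is a cyclic sequence of signed gene labels: sign + means the
gene lies on the heavy strand, − on the light strand.  Two orders are
equal iff one is a rotation of the other; whole-genome reflection with
sign flip is *not* an equality by default (strands are biologically
distinguishable), though the breakpoint distance — like any
adjacency-based distance on circular genomes — cannot separate an order
from its reflected complement.

Adjacencies record neighbour identity and relative orientation; the
breakpoint distance between two orders on the same label set is the
number of adjacencies of one absent from the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .vocab import normalize_label

logger = logging.getLogger(__name__)

Token = tuple[str, int]  # (canonical label, +1 or -1)


class IncomparableOrdersError(ValueError):
    """Two orders do not share the same label set."""


@dataclass(frozen=True)
class GeneOrder:
    """Signed circular permutation of unique gene labels."""

    tokens: tuple[Token, ...]
    species: str = ""

    def __post_init__(self) -> None:
        labels = [t[0] for t in self.tokens]
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate label(s) in order: {dup}")
        if any(s not in (1, -1) for _, s in self.tokens):
            raise ValueError("token signs must be +1 or -1")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(t[0] for t in self.tokens)

    def rotations(self):
        n = len(self.tokens)
        for k in range(n):
            yield self.tokens[k:] + self.tokens[:k]

    def equals(self, other: "GeneOrder", chirality_insensitive: bool = False) -> bool:
        """Equality as circular orders (rotation; optionally reflection)."""
        if self.labels != other.labels:
            return False
        mine = set(self.rotations())
        if other.tokens in mine:
            return True
        if chirality_insensitive:
            return reflect(other).tokens in mine
        return False


def reflect(o: GeneOrder) -> GeneOrder:
    """Reverse reading direction and flip every sign."""
    return GeneOrder(
        tokens=tuple((lab, -s) for lab, s in reversed(o.tokens)),
        species=o.species,
    )


def parse_order(text: str, species: str = "") -> GeneOrder:
    """Parse a whitespace-separated order string.

    A leading ``-`` marks a light-strand gene; labels may use either the
    full (``trnL2``) or one-letter (``L2``) vocabulary.
    """
    parts = text.split()
    if not parts:
        raise ValueError("empty order")
    tokens: list[Token] = []
    for p in parts:
        sign = 1
        if p.startswith("-"):
            sign, p = -1, p[1:]
        tokens.append((normalize_label(p), sign))
    return GeneOrder(tokens=tuple(tokens), species=species)


def format_order(o: GeneOrder, short: bool = False) -> str:
    """Order string that round-trips through parse_order."""
    from .vocab import short_code

    parts = []
    for lab, s in o.tokens:
        disp = short_code(lab) if short else lab
        parts.append(disp if s > 0 else f"-{disp}")
    return " ".join(parts)


def canonical_rotation(o: GeneOrder, anchor: str = "cox1") -> GeneOrder:
    """Rotate so *anchor* comes first with positive sign.

    If the anchor sits on the minus strand the whole order is reflected
    (reading direction reversed, all signs flipped) before rotating, so
    the canonical form always starts ``+anchor``.
    """
    anchor = normalize_label(anchor)
    if anchor not in o.labels:
        raise ValueError(f"anchor not found: {anchor}")
    work = o
    idx, sign = next(
        (i, s) for i, (lab, s) in enumerate(work.tokens) if lab == anchor
    )
    if sign < 0:
        work = reflect(work)
        idx = next(i for i, (lab, _) in enumerate(work.tokens) if lab == anchor)
    toks = work.tokens[idx:] + work.tokens[:idx]
    return GeneOrder(tokens=toks, species=o.species)


def _canon_adj(a: Token, b: Token) -> tuple[Token, Token]:
    # an adjacency read in the opposite direction is the same contact
    fwd = (a, b)
    rev = ((b[0], -b[1]), (a[0], -a[1]))
    return min(fwd, rev)


def adjacency_set(o: GeneOrder, signed: bool = True) -> frozenset:
    """Set of neighbour contacts of a circular order.

    Signed mode keeps relative orientation (an adjacency and its reverse
    complement are identified); unsigned mode reduces each contact to the
    unordered label pair.  For n unique labels (n >= 3) the set has
    exactly n elements.
    """
    if len(o) < 2:
        raise ValueError("adjacency_set needs at least 2 tokens")
    toks = o.tokens
    n = len(toks)
    if signed:
        return frozenset(_canon_adj(toks[i], toks[(i + 1) % n]) for i in range(n))
    return frozenset(
        frozenset((toks[i][0], toks[(i + 1) % n][0])) for i in range(n)
    )


def breakpoint_distance(o1: GeneOrder, o2: GeneOrder, signed: bool = True) -> int:
    """Number of adjacencies of o1 absent from o2.

    Symmetric on identical label sets; 0 iff the orders coincide as
    circular orders (up to reflection-with-sign-flip in signed mode).
    """
    if o1.labels != o2.labels:
        diff = sorted(o1.labels ^ o2.labels)
        raise IncomparableOrdersError(f"incomparable orders; differing labels: {diff}")
    a1 = adjacency_set(o1, signed=signed)
    a2 = adjacency_set(o2, signed=signed)
    return len(a1 - a2)


def shared_adjacencies(o1: GeneOrder, o2: GeneOrder, signed: bool = True) -> int:
    if o1.labels != o2.labels:
        common = o1.labels & o2.labels
        o1 = restrict(o1, common)
        o2 = restrict(o2, common)
    return len(adjacency_set(o1, signed=signed) & adjacency_set(o2, signed=signed))


def restrict(o: GeneOrder, labels: frozenset[str] | set[str]) -> GeneOrder:
    """Drop tokens outside *labels*, keeping circular order."""
    kept = tuple(t for t in o.tokens if t[0] in labels)
    dropped = len(o) - len(kept)
    if dropped:
        logger.info("restricted %s: dropped %d token(s)", o.species or "order", dropped)
    return GeneOrder(tokens=kept, species=o.species)


def similarity_matrix(
    orders: list[GeneOrder], signed: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise shared-adjacency counts and breakpoint distances.

    Orders with differing label sets are restricted to the common label
    set (logged).  Returns (shared, breakpoints) DataFrames indexed by
    species name.
    """
    if len(orders) < 2:
        raise ValueError("need at least 2 orders")
    common = frozenset.intersection(*(o.labels for o in orders))
    if len(common) < 3:
        raise IncomparableOrdersError("fewer than 3 labels shared by all orders")
    rs = [restrict(o, common) for o in orders]
    names = [o.species or f"order{i}" for i, o in enumerate(rs)]
    adjs = [adjacency_set(o, signed=signed) for o in rs]
    n = len(rs)
    shared = [[len(adjs[i] & adjs[j]) for j in range(n)] for i in range(n)]
    bp = [[len(adjs[i] - adjs[j]) for j in range(n)] for i in range(n)]
    return (
        pd.DataFrame(shared, index=names, columns=names),
        pd.DataFrame(bp, index=names, columns=names),
    )


def read_order_file(path: str | Path) -> list[GeneOrder]:
    """Read ``species<TAB>token token ...`` lines into orders."""
    orders = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        species, _, rest = line.partition("\t")
        if not rest:
            raise ValueError(f"malformed order line (no tab): {line[:40]!r}")
        orders.append(parse_order(rest, species=species.strip()))
    return orders


def write_order_file(orders: list[GeneOrder], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for o in orders:
            fh.write(f"{o.species}\t{format_order(o)}\n")
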