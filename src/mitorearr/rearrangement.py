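"""Tandem-duplication/random-loss (TDRL) + translocation machinery.

Under the TDRL model a contiguous gene block is duplicated in tandem and
the redundant copy of each gene is subsequently lost; which copy survives
per gene determines the net reordering.  Together with block
translocations (recombination-mediated moves) this is the standard
desk-scale model for mitochondrial gene-order evolution.  No inversion
operation is modelled: strand flips make scenario verification fail
loudly rather than silently succeed.

Three primitive operations are provided (tandem_duplicate_block,
delete_copies, translocate_block) plus the composite ``tdrl`` event
(duplication + loss mask applied atomically), which is the unit counted
by the scenario search: one TDRL event = one op, one translocation = one
op.

``scenario_search`` enumerates *all* minimal-length scenarios between two
orders by iterative deepening with a meet-in-the-middle strategy:
forward composite moves from the source are intersected with predecessor
states of the target (the TDRL predecessor of an order replaces a
contiguous region X·Y by an interleaving of X and Y; translocations are
closed under inversion).  Scenarios are deduplicated up to identical
sequences of intermediate orders and returned in a deterministic
lexicographic enumeration order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .gene_order import GeneOrder, Token
from .vocab import label_type

TANDEM_DUPLICATE = "tandem_duplicate_block"
DELETE_COPIES = "delete_copies"
TRANSLOCATE = "translocate_block"
TDRL = "tdrl"

OP_KINDS = (TANDEM_DUPLICATE, DELETE_COPIES, TRANSLOCATE, TDRL)


class OpError(ValueError):
    """An operation cannot be applied to the given order."""


class SearchTooLargeError(RuntimeError):
    """The scenario search space exceeds the configured guard."""


@dataclass(frozen=True)
class RearrangementOp:
    """One rearrangement operation.

    kind-specific params:
      tandem_duplicate_block: none
      delete_copies / tdrl:   ``keep`` — per-label surviving copy (1 = the
                              first occurrence in reading order, 2 = the
                              second)
      translocate_block:      ``after`` or ``before`` — label naming the
                              insertion point
    """

    kind: str
    block: tuple[str, ...]
    keep: Optional[tuple[tuple[str, int], ...]] = None
    after: Optional[str] = None
    before: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in OP_KINDS:
            raise ValueError(f"unknown op kind: {self.kind!r}")
        if self.kind in (DELETE_COPIES, TDRL) and self.keep is None:
            raise ValueError(f"{self.kind} requires a keep mask")
        if self.kind == TRANSLOCATE and (self.after is None) == (self.before is None):
            raise ValueError("translocate_block requires exactly one of after/before")

    @property
    def keep_map(self) -> dict[str, int]:
        return dict(self.keep or ())

    def to_json(self) -> dict:
        d: dict = {"kind": self.kind, "block": list(self.block)}
        if self.keep is not None:
            d["keep"] = {lab: c for lab, c in self.keep}
        if self.after is not None:
            d["after"] = self.after
        if self.before is not None:
            d["before"] = self.before
        return d

    @classmethod
    def from_json(cls, d: dict) -> "RearrangementOp":
        keep = d.get("keep")
        return cls(
            kind=d["kind"],
            block=tuple(d["block"]),
            keep=tuple(sorted(keep.items())) if keep else None,
            after=d.get("after"),
            before=d.get("before"),
        )


def make_tdrl(block: tuple[str, ...], keep: dict[str, int]) -> RearrangementOp:
    if set(keep) != set(block):
        raise ValueError("keep mask must cover exactly the block labels")
    if any(c not in (1, 2) for c in keep.values()):
        raise ValueError("keep mask entries must be 1 or 2")
    return RearrangementOp(kind=TDRL, block=block, keep=tuple(sorted(keep.items())))


def make_translocation(
    block: tuple[str, ...], after: str | None = None, before: str | None = None
) -> RearrangementOp:
    return RearrangementOp(kind=TRANSLOCATE, block=block, after=after, before=before)


# ---------------------------------------------------------------------------
# applying operations to (possibly duplicate-containing) token sequences

def _labels(tokens: tuple[Token, ...]) -> list[str]:
    return [t[0] for t in tokens]


def _find_block(tokens: tuple[Token, ...], block: tuple[str, ...]) -> tuple[tuple[Token, ...], int]:
    """Locate *block* as a contiguous circular run of labels.

    Returns a rotation of *tokens* in which the block is linearly
    contiguous, plus its start index.  Raises OpError when the block is
    not contiguous.
    """
    n = len(tokens)
    l = len(block)
    if l > n:
        raise OpError(f"block longer than order: {block}")
    labs = _labels(tokens)
    for s in range(n):
        if all(labs[(s + k) % n] == block[k] for k in range(l)):
            if s + l <= n:
                return tokens, s
            rot = tokens[s:] + tokens[:s]
            return rot, 0
    raise OpError(f"block not contiguous: {block}")


def apply_op(tokens: tuple[Token, ...], op: RearrangementOp) -> tuple[Token, ...]:
    """Apply one operation to a circular signed token sequence.

    The sequence may contain duplicate labels between a duplication and
    its deletion; every other operation requires its block labels to be
    unambiguous.  Token multiset is conserved except by explicit
    deletion.
    """
    if op.kind == TANDEM_DUPLICATE:
        toks, s = _find_block(tokens, op.block)
        blk = toks[s:s + len(op.block)]
        return toks[:s + len(op.block)] + blk + toks[s + len(op.block):]

    if op.kind == DELETE_COPIES:
        return _delete_copies(tokens, op)

    if op.kind == TDRL:
        dup = RearrangementOp(kind=TANDEM_DUPLICATE, block=op.block)
        dele = RearrangementOp(kind=DELETE_COPIES, block=op.block, keep=op.keep)
        return _delete_copies(apply_op(tokens, dup), dele)

    if op.kind == TRANSLOCATE:
        toks, s = _find_block(tokens, op.block)
        l = len(op.block)
        blk = toks[s:s + l]
        rest = toks[:s] + toks[s + l:]
        labs = _labels(rest)
        anchor = op.after if op.after is not None else op.before
        if labs.count(anchor) != 1:
            raise OpError(f"insertion anchor {anchor!r} not unique in order")
        j = labs.index(anchor) + (1 if op.after is not None else 0)
        return rest[:j] + blk + rest[j:]

    raise OpError(f"unknown op kind: {op.kind!r}")


def _delete_copies(tokens: tuple[Token, ...], op: RearrangementOp) -> tuple[Token, ...]:
    keep = op.keep_map
    if set(keep) != set(op.block):
        raise OpError("keep mask must cover exactly the block labels")
    labs = _labels(tokens)
    for lab in op.block:
        if labs.count(lab) != 2:
            raise OpError(
                f"delete_copies expects exactly 2 copies of {lab!r}, found {labs.count(lab)}"
            )
    out: list[Token] = []
    seen: dict[str, int] = {}
    for tok in tokens:
        lab = tok[0]
        if lab in keep:
            seen[lab] = seen.get(lab, 0) + 1
            if seen[lab] != keep[lab]:
                continue  # this copy is lost
        out.append(tok)
    res_labs = _labels(tuple(out))
    dup = sorted({x for x in res_labs if res_labs.count(x) > 1})
    if dup:
        raise OpError(f"ambiguous survivor: two copies left of {dup}")
    return tuple(out)


# ---------------------------------------------------------------------------
# scenarios

@dataclass
class RearrangementScenario:
    """Ordered list of operations taking *source* to *target*."""

    ops: list[RearrangementOp]
    source: GeneOrder
    target: GeneOrder

    @property
    def involved(self) -> frozenset[str]:
        """Labels occurring in any duplicated or translocated block."""
        labs: set[str] = set()
        for op in self.ops:
            if op.kind in (TANDEM_DUPLICATE, TDRL, TRANSLOCATE):
                labs.update(op.block)
        return frozenset(labs)

    def involved_tally(self) -> dict[str, int]:
        """Involved-gene count by feature type (tRNA/PCG/rRNA/CR)."""
        tally: dict[str, int] = {}
        for lab in self.involved:
            t = label_type(lab)
            tally[t] = tally.get(t, 0) + 1
        return tally

    def intermediate_states(self) -> list[tuple[Token, ...]]:
        """Token sequences after each op (canonical rotations)."""
        states = []
        toks = self.source.tokens
        for op in self.ops:
            toks = apply_op(toks, op)
            states.append(_canon(toks))
        return states

    def to_json(self) -> dict:
        from .gene_order import format_order

        return {
            "source": format_order(self.source),
            "target": format_order(self.target),
            "ops": [op.to_json() for op in self.ops],
        }

    @classmethod
    def from_json(cls, d: dict) -> "RearrangementScenario":
        from .gene_order import parse_order

        return cls(
            ops=[RearrangementOp.from_json(o) for o in d["ops"]],
            source=parse_order(d["source"]),
            target=parse_order(d["target"]),
        )


@dataclass
class ScenarioVerdict:
    success: bool
    final: Optional[GeneOrder]
    involved_tally: dict[str, int] = field(default_factory=dict)
    failed_step: Optional[int] = None
    message: str = ""


def verify_scenario(s: RearrangementScenario) -> ScenarioVerdict:
    """Apply the scenario and compare the outcome to the target.

    Success iff every op applies cleanly and the final sequence equals
    the target as a circular signed order (rotation equality).
    """
    toks = s.source.tokens
    for i, op in enumerate(s.ops):
        try:
            toks = apply_op(toks, op)
        except OpError as e:
            return ScenarioVerdict(
                success=False, final=None, failed_step=i, message=str(e)
            )
    labs = _labels(toks)
    if len(set(labs)) != len(labs):
        return ScenarioVerdict(
            success=False, final=None, message="final order contains duplicates"
        )
    final = GeneOrder(tokens=toks, species=s.source.species)
    ok = final.equals(s.target)
    return ScenarioVerdict(
        success=ok,
        final=final,
        involved_tally=s.involved_tally() if ok else {},
        message="" if ok else "final order differs from target",
    )


# ---------------------------------------------------------------------------
# minimal-scenario search

def _canon(tokens: tuple[Token, ...]) -> tuple[Token, ...]:
    """Canonical rotation: lexicographically least among all rotations."""
    n = len(tokens)
    return min(tokens[k:] + tokens[:k] for k in range(n))


def _forward_moves(
    state: tuple[Token, ...], max_block: int
) -> Iterator[tuple[RearrangementOp, tuple[Token, ...]]]:
    """All composite moves (TDRL event, translocation) from a state.

    Enumeration order is fixed: by block start, block length, then mask /
    insertion point.
    """
    n = len(state)
    cap = min(max_block, n - 1)
    for s in range(n):
        for l in range(1, cap + 1):
            blk = tuple(state[(s + k) % n] for k in range(l))
            blk_labels = tuple(t[0] for t in blk)
            rest = tuple(state[(s + l + k) % n] for k in range(n - l))
            # TDRL events: every proper two-subsequence split of the block
            if l >= 2:
                for mask in itertools.product((1, 2), repeat=l):
                    if all(mask[i] <= mask[i + 1] for i in range(l - 1)):
                        continue  # monotone masks are identities
                    c1 = tuple(blk[i] for i in range(l) if mask[i] == 1)
                    c2 = tuple(blk[i] for i in range(l) if mask[i] == 2)
                    new = _canon(c1 + c2 + rest)
                    op = make_tdrl(
                        blk_labels, dict(zip(blk_labels, mask))
                    )
                    yield op, new
            # translocations: insert the block after each other element
            for j in range(1, n - l):  # j = 0 reproduces the original order
                anchor = rest[j - 1][0]
                new = _canon(rest[:j] + blk + rest[j:])
                yield make_translocation(blk_labels, after=anchor), new


def _backward_moves(
    state: tuple[Token, ...], max_block: int
) -> Iterator[tuple[RearrangementOp, tuple[Token, ...]]]:
    """Predecessor states p with the completing op mapping p -> state.

    Translocations are closed under inversion.  A TDRL predecessor
    replaces a contiguous region X·Y of the state by a proper
    interleaving of X and Y (the event then sorts it back out).
    """
    n = len(state)
    cap = min(max_block, n - 1)
    for s in range(n):
        for l in range(1, cap + 1):
            blk = tuple(state[(s + k) % n] for k in range(l))
            blk_labels = tuple(t[0] for t in blk)
            rest = tuple(state[(s + l + k) % n] for k in range(n - l))
            # inverse translocation: move the block somewhere else in p;
            # the completing op moves it back after its current
            # predecessor in the state.
            dest_anchor = state[(s - 1) % n][0]
            for j in range(1, n - l):
                pred = _canon(rest[:j] + blk + rest[j:])
                yield make_translocation(blk_labels, after=dest_anchor), pred
            # inverse TDRL: region = X·Y; predecessor interleaves X and Y
            if l >= 2:
                for k in range(1, l):
                    x, y = blk[:k], blk[k:]
                    for positions in itertools.combinations(range(l), k):
                        if positions == tuple(range(k)):
                            continue  # trivial interleaving = state itself
                        inter: list[Token] = [None] * l  # type: ignore[list-item]
                        xi = iter(x)
                        yi = iter(y)
                        pos_set = set(positions)
                        for i in range(l):
                            inter[i] = next(xi) if i in pos_set else next(yi)
                        pred_blk = tuple(inter)
                        pred = _canon(pred_blk + rest)
                        mask = {
                            pred_blk[i][0]: (1 if i in pos_set else 2)
                            for i in range(l)
                        }
                        op = make_tdrl(tuple(t[0] for t in pred_blk), mask)
                        yield op, pred


def _expand_layer(
    layer: dict[tuple, list[tuple[tuple, tuple]]],
    mover,
    max_block: int,
) -> dict[tuple, list[tuple[tuple, tuple]]]:
    """One BFS layer: state -> list of (state_path, op_path) entries.

    Paths are deduplicated by their state sequence (one representative op
    list per distinct sequence of intermediate orders).
    """
    out: dict[tuple, dict[tuple, tuple]] = {}
    for state, entries in layer.items():
        for op, new in mover(state, max_block):
            for spath, opath in entries:
                key = spath + (state,)
                slot = out.setdefault(new, {})
                if key not in slot:
                    slot[key] = opath + (op,)
    return {st: sorted((sp, op) for sp, op in d.items()) for st, d in out.items()}


def scenario_search(
    source: GeneOrder,
    target: GeneOrder,
    max_ops: int = 4,
    max_block: int = 7,
    guard: int = 5_000_000,
) -> list[RearrangementScenario]:
    """All minimal scenarios (composite ops) taking source to target.

    Iterative deepening over op count 0..max_ops; within each depth a
    meet-in-the-middle join of forward moves from the source and
    predecessor moves of the target.  Returns every scenario of the
    minimal op count, deduplicated up to identical intermediate-order
    sequences, in deterministic lexicographic order.
    """
    if source.labels != target.labels:
        diff = sorted(source.labels ^ target.labels)
        raise ValueError(f"incomparable orders; differing labels: {diff}")
    n = len(source)
    moves_per_state = n * (2 ** min(max_block, n - 1) + n)
    src = _canon(source.tokens)
    tgt = _canon(target.tokens)

    if src == tgt:
        return [RearrangementScenario(ops=[], source=source, target=target)]

    for depth in range(1, max_ops + 1):
        f_levels = (depth + 1) // 2
        b_levels = depth // 2
        if moves_per_state ** max(f_levels, b_levels) > guard:
            raise SearchTooLargeError(
                f"search too large: ~{moves_per_state}^{max(f_levels, b_levels)} states at depth {depth}"
            )
        fwd: dict = {src: [((), ())]}
        for _ in range(f_levels):
            fwd = _expand_layer(fwd, _forward_moves, max_block)
        bwd: dict = {tgt: [((), ())]}
        for _ in range(b_levels):
            bwd = _expand_layer(bwd, _backward_moves, max_block)

        found: dict[tuple, RearrangementScenario] = {}
        for mid in sorted(set(fwd) & set(bwd)):
            for f_states, f_ops in fwd[mid]:
                for b_states, b_ops in bwd[mid]:
                    # backward paths list states from target inward;
                    # completing ops run mid -> ... -> target in order
                    seq_states = f_states[1:] + (mid,) + tuple(reversed(b_states[1:]))
                    key = seq_states
                    if key in found:
                        continue
                    ops = list(f_ops) + list(reversed(b_ops))
                    scen = RearrangementScenario(
                        ops=ops, source=source, target=target
                    )
                    if verify_scenario(scen).success:
                        found[key] = scen
        if found:
            return [found[k] for k in sorted(found)]
    return []
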