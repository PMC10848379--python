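"""Seeded generators for annotated circular genomes and rearranged orders.

The generator emulates a small-crustacean mitogenome: a ~15 kb circle
carrying 13 PCGs, 22 tRNAs, 2 rRNAs and one AT-rich control region, with
strand-asymmetric, strongly AT-biased base composition (AT ≈ 74%), small
overlaps between neighbouring genes and short intergenic spacers.  Every
generator takes an explicit seed and is byte-deterministic given it, and
each simulated dataset carries its ground truth (the feature plan, the
base probabilities, any planted rearrangement events) so downstream
statistics can be checked against what was actually put in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .gene_order import GeneOrder
from .genome_model import AnnotatedGenome, GeneFeature, reverse_complement
from .rearrangement import (
    RearrangementOp,
    RearrangementScenario,
    apply_op,
    make_tdrl,
    make_translocation,
)
from .vocab import CONTROL_REGION, PCG

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: default heavy-strand base probabilities, matching the AT-rich,
#: mildly A-skewed composition typical of this clade (AT ~ 74%)
DEFAULT_BASE_PROBS = {
    "H": {"A": 0.3778, "C": 0.1601, "G": 0.0970, "T": 0.3651},
    "L": {"A": 0.3651, "C": 0.0970, "G": 0.1601, "T": 0.3778},
}


@dataclass(frozen=True)
class PlanEntry:
    """One planned feature: name, type, length, strand, gap to the next.

    ``gap_after`` is the number of intergenic bp before the next feature;
    negative values overlap the next feature by that many bp.
    """

    name: str
    type: str
    length: int
    strand: str
    gap_after: int = 0


@dataclass
class SimulationTruth:
    """Everything needed to regenerate and verify a simulated genome."""

    seed: int
    feature_plan: list[PlanEntry]
    base_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            s: dict(p) for s, p in DEFAULT_BASE_PROBS.items()
        }
    )
    total_length: Optional[int] = None
    planted_ops: Optional[RearrangementScenario] = None

    def __post_init__(self) -> None:
        for strand, probs in self.base_probs.items():
            tot = sum(probs.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"base_probs[{strand}] sum to {tot}, not 1")

    @property
    def planned_length(self) -> int:
        return sum(e.length + e.gap_after for e in self.feature_plan)


def default_truth(seed: int = 0) -> SimulationTruth:
    """Study-condition defaults: a plan mirroring the packaged porcelain-
    crab annotation (same names, lengths, strands and gaps) with the
    clade-typical AT-rich base probabilities."""
    from . import reference

    genome = reference.load_annotation()
    feats = sorted(genome.features, key=lambda f: (f.start, -(f.end - f.start)))
    L = genome.length
    plan = []
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        if i == len(feats) - 1:
            gap = (nxt.start + L) - f.end - 1
        else:
            gap = nxt.start - f.end - 1
        plan.append(
            PlanEntry(
                name=f.name, type=f.type,
                length=f.end - f.start + 1,
                strand=f.strand, gap_after=gap,
            )
        )
    return SimulationTruth(seed=seed, feature_plan=plan)


def simulate_genome(truth: SimulationTruth) -> AnnotatedGenome:
    """Build an annotated genome realising *truth*.

    The circle is drawn i.i.d. from the heavy-strand base probabilities;
    regions covered by a light-strand feature are drawn from the
    light-strand probabilities on the sense strand and stored as their
    complement.  PCGs are given an explicit start codon (ATG) and
    terminator (TAA, truncated to T/TA when the planned length is not a
    codon multiple) on the sense strand.  Where planned features overlap,
    the later feature's sequence wins in the shared bp.
    """
    L = truth.planned_length
    if truth.total_length is not None:
        if L > truth.total_length:
            raise ValueError(
                f"plan exceeds genome length: plan {L} > declared {truth.total_length}"
            )
        L = truth.total_length
    if L <= 0 or not truth.feature_plan:
        raise ValueError("empty or inconsistent feature plan")

    rng = np.random.default_rng(truth.seed)
    bases = np.array(list("ACGT"))
    probs_h = np.array([truth.base_probs["H"][b] for b in "ACGT"])
    seq = rng.choice(bases, size=L, p=probs_h)

    # lay out features along the circle
    features: list[GeneFeature] = []
    pos = 1
    for entry in truth.feature_plan:
        start = (pos - 1) % L + 1
        end_abs = start + entry.length - 1
        wraps = end_abs > L
        end = end_abs - L if wraps else end_abs
        sense = _feature_sequence(entry, truth, rng)
        stored = reverse_complement(sense) if entry.strand == "L" else sense
        for k, ch in enumerate(stored):
            seq[(start - 1 + k) % L] = ch
        features.append(
            GeneFeature(
                name=entry.name, type=entry.type,
                start=start, end=end, strand=entry.strand, wraps=wraps,
            )
        )
        pos = start + entry.length + entry.gap_after

    genome = AnnotatedGenome(
        seq="".join(seq),
        features=sorted(features, key=lambda f: (f.start, -(f.end - f.start))),
        name=f"sim_seed{truth.seed}",
        declared_length=L,
    )
    genome.validate()
    return genome


def _feature_sequence(entry: PlanEntry, truth: SimulationTruth, rng) -> str:
    probs = truth.base_probs.get(entry.strand, truth.base_probs["H"])
    bases = np.array(list("ACGT"))
    p = np.array([probs[b] for b in "ACGT"])
    body = rng.choice(bases, size=entry.length, p=p)
    s = "".join(body)
    if entry.type == PCG and entry.length >= 9:
        tail = entry.length % 3
        if tail:
            s = "ATG" + s[3: entry.length - tail - 3] + "TAA" + "TA"[:tail]
        else:
            s = "ATG" + s[3: entry.length - 3] + "TAA"
    return s


def synthetic_sequence_from_composition(
    counts: dict[str, int], seed: int = 0
) -> str:
    """Synthetic stand-in sequence with exact per-base counts.

    Builds a deterministic random arrangement of exactly ``counts[b]``
    copies of each base.  This is a *synthetic* surrogate used when a
    deposited genome sequence is unavailable: it reproduces composition
    and skew statistics exactly (they depend only on counts) but carries
    no gene structure.
    """
    rng = np.random.default_rng(seed)
    arr = np.array(
        [b for base, n in sorted(counts.items()) for b in base * n], dtype="<U1"
    )
    rng.shuffle(arr)
    return "".join(arr)


def simulate_rearranged_order(
    reference: GeneOrder,
    n_events: int,
    seed: int,
    max_block: int = 7,
) -> tuple[GeneOrder, RearrangementScenario]:
    """Apply *n_events* random composite events to a reference order.

    Each event is a TDRL (random contiguous block of 2..max_block genes,
    random non-trivial loss mask) or a translocation (block of
    1..max_block genes to a random new position), equiprobable.  Returns
    the derived order and the recorded ground-truth scenario, which
    always verifies against it.
    """
    rng = np.random.default_rng(seed)
    n = len(reference)
    cap = min(max_block, n - 1)
    toks = reference.tokens
    ops: list[RearrangementOp] = []
    for _ in range(n_events):
        op = _random_event(toks, rng, cap)
        ops.append(op)
        toks = apply_op(toks, op)
    final = GeneOrder(tokens=toks, species=f"{reference.species}+{n_events}ev")
    scen = RearrangementScenario(ops=ops, source=reference, target=final)
    return final, scen


def _random_event(toks, rng, cap: int) -> RearrangementOp:
    n = len(toks)
    labs = [t[0] for t in toks]
    kind = rng.choice(["tdrl", "translocation"])
    if kind == "tdrl" and cap >= 2:
        l = int(rng.integers(2, cap + 1))
        s = int(rng.integers(0, n))
        block = tuple(labs[(s + k) % n] for k in range(l))
        while True:
            mask = tuple(int(m) for m in rng.integers(1, 3, size=l))
            if any(mask[i] > mask[i + 1] for i in range(l - 1)):
                break  # non-monotone => non-identity
        return make_tdrl(block, dict(zip(block, mask)))
    l = int(rng.integers(1, min(cap, n - 2) + 1))
    s = int(rng.integers(0, n))
    block = tuple(labs[(s + k) % n] for k in range(l))
    rest = [labs[(s + l + k) % n] for k in range(n - l)]
    j = int(rng.integers(1, n - l))  # j=0 would reproduce the input
    return make_translocation(block, after=rest[j - 1])
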