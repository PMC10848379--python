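"""Overlaps, intergenic spacers and coverage bookkeeping on the circle.

Overlap is defined on the arc intersection of *any* unordered feature
pair (not just rank-adjacent ones), which captures nested and offset
cases; strand is ignored.  The control region is excluded from overlap
counting by default — mitogenome papers count gene/gene overlaps, and
the CR commonly abuts or marginally overlaps its flanking tRNA — but can
be included with a flag.

Spacers are computed between rank-adjacent features only (sorted by
start, wrapping across the origin), as gap = next.start − this.end − 1;
only positive gaps are reported.  The CR counts as a feature for spacer
purposes, never as a spacer itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_model import AnnotatedGenome, GeneFeature
from .vocab import CONTROL_REGION


@dataclass
class AdjacencyReport:
    """Aggregate overlap/spacer bookkeeping for one annotation."""

    overlaps: list[tuple[str, str, int]]
    spacers: list[tuple[str, str, int]]
    gap_after: dict[str, int] = field(default_factory=dict)

    @property
    def totals(self) -> dict[str, int]:
        gaps = [g for *_, g in self.spacers]
        return {
            "overlap_count": len(self.overlaps),
            "overlap_total_bp": sum(o for *_, o in self.overlaps),
            "spacer_count": len(gaps),
            "spacer_total_bp": sum(gaps),
            "spacer_min_bp": min(gaps) if gaps else 0,
            "spacer_max_bp": max(gaps) if gaps else 0,
        }


def _arc_intersection(a: GeneFeature, b: GeneFeature, L: int) -> int:
    """Length in bp of the intersection of two circular arcs.

    Positions shared by both features are counted once per pair even
    under triple overlap elsewhere.
    """
    total = 0
    for (s1, e1) in a.intervals(L):
        for (s2, e2) in b.intervals(L):
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def pairwise_overlaps(
    genome: AnnotatedGenome, include_control_region: bool = False
) -> list[tuple[str, str, int]]:
    """All unordered feature pairs whose circular arcs intersect.

    Returns (name_a, name_b, overlap_bp) in start order.  The control
    region is skipped unless *include_control_region*.
    """
    L = genome.length
    feats = [
        f
        for f in sorted(genome.features, key=lambda f: (f.start, -(f.end - f.start)))
        if include_control_region or f.type != CONTROL_REGION
    ]
    out = []
    for i, a in enumerate(feats):
        for b in feats[i + 1:]:
            ov = _arc_intersection(a, b, L)
            if ov > 0:
                out.append((a.name, b.name, ov))
    return out


def _sorted_circular(genome: AnnotatedGenome) -> list[GeneFeature]:
    return sorted(genome.features, key=lambda f: (f.start, -(f.end - f.start)))


def intergenic_spacers(genome: AnnotatedGenome) -> list[tuple[str, str, int]]:
    """Positive gaps between rank-adjacent features, wrapping the origin.

    Returns (this_feature, next_feature, gap_bp).
    """
    feats = _sorted_circular(genome)
    if not feats:
        return []
    L = genome.length
    out = []
    for i, cur in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        cur_end = cur.end if not cur.wraps else cur.end + L  # wrap end in next cycle
        if i == len(feats) - 1:
            gap = (nxt.start + L) - cur_end - 1
        else:
            gap = nxt.start - cur.end - 1
        if gap > 0:
            out.append((cur.name, nxt.name, gap))
    return out


def geometry_summary(
    genome: AnnotatedGenome, include_control_region: bool = False
) -> AdjacencyReport:
    """Overlaps + spacers + per-feature gap-after values in one report."""
    overlaps = pairwise_overlaps(genome, include_control_region)
    spacers = intergenic_spacers(genome)
    feats = _sorted_circular(genome)
    gap_after: dict[str, int] = {}
    L = genome.length
    for i, cur in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        if i == len(feats) - 1:
            gap = (nxt.start + L) - cur.end - 1
        else:
            gap = nxt.start - cur.end - 1
        gap_after[cur.name] = gap
    return AdjacencyReport(overlaps=overlaps, spacers=spacers, gap_after=gap_after)
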