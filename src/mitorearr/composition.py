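"""Nucleotide composition and strand-skew statistics.

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), computed over a
region of interest.  Skews are scale-invariant, so counts and percentages
give identical values.  Per-gene statistics are computed on the coding
(sense) strand: light-strand genes are reverse-complemented first, which
is the convention under which the strand asymmetry of the protein-coding
set (negative AT-skew, slightly positive GC-skew in this clade) is
reproduced.

Percentages are computed over counted A/C/G/T only; ambiguity code N is
permitted in the sequence but excluded from numerator and denominator.
Report rounding is half-up — 2 decimals for percentages, 3 for skews —
while internal values keep full precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .genome_model import AnnotatedGenome, extract_feature_sequence
from .vocab import CONTROL_REGION, PCG, RRNA, TRNA


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.0545 -> 0.055 at 3 digits)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Composition:
    """Base percentages, AT content and skews for one region."""

    a_pct: float
    t_pct: float
    g_pct: float
    c_pct: float
    at_pct: float
    at_skew: float
    gc_skew: float
    length: int

    def rounded(self) -> "Composition":
        return Composition(
            a_pct=round_half_up(self.a_pct, 2),
            t_pct=round_half_up(self.t_pct, 2),
            g_pct=round_half_up(self.g_pct, 2),
            c_pct=round_half_up(self.c_pct, 2),
            at_pct=round_half_up(self.at_pct, 2),
            at_skew=round_half_up(self.at_skew, 3),
            gc_skew=round_half_up(self.gc_skew, 3),
            length=self.length,
        )


def at_skew(a: float, t: float) -> float:
    """(A − T)/(A + T); accepts counts or percentages."""
    if a + t == 0:
        raise ValueError("undefined skew: A + T = 0")
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> float:
    """(G − C)/(G + C); accepts counts or percentages."""
    if g + c == 0:
        raise ValueError("undefined skew: G + C = 0")
    return (g - c) / (g + c)


def base_counts(seq: str) -> dict[str, int]:
    s = seq.upper()
    return {b: s.count(b) for b in "ACGT"}


def base_composition(seq: str) -> Composition:
    """Composition of a sequence; N excluded from all percentages."""
    if not seq:
        raise ValueError("empty sequence")
    counts = base_counts(seq)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no countable bases (all ambiguous)")
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    return Composition(
        a_pct=100 * a / n,
        t_pct=100 * t / n,
        g_pct=100 * g / n,
        c_pct=100 * c / n,
        at_pct=100 * (a + t) / n,
        at_skew=at_skew(a, t) if a + t else 0.0,
        gc_skew=gc_skew(g, c) if g + c else 0.0,
        length=len(seq),
    )


#: fixed row order of the regional report
REPORT_COLUMNS = ("A%", "T%", "G%", "C%", "(AT)%", "AT-skew", "GC-skew", "Length (bp)")


def region_report(genome: AnnotatedGenome) -> dict[str, Composition]:
    """Composition table over the standard mitogenome regions.

    Rows: the whole mitogenome (as-stored heavy strand), the 13 PCGs
    concatenated then each individually, all tRNAs concatenated, both
    rRNAs concatenated, and the AT-rich control region — all gene regions
    on the coding (sense) strand.  Missing feature classes drop their row
    with a warning.
    """
    if not genome.has_sequence:
        raise ValueError("sequence not loaded")
    report: dict[str, Composition] = {}
    report["Mitogenome"] = base_composition(genome.seq)

    def concat(ftype: str) -> str:
        return "".join(
            extract_feature_sequence(genome, f.name)
            for f in genome.features
            if f.type == ftype
        )

    pcg_cat = concat(PCG)
    if pcg_cat:
        report["PCGs"] = base_composition(pcg_cat)
        for f in genome.features_of_type(PCG):
            report[f.name] = base_composition(
                extract_feature_sequence(genome, f.name)
            )
    else:
        warnings.warn("no protein-coding genes; PCG rows omitted", stacklevel=2)

    for key, ftype in (("tRNAs", TRNA), ("rRNAs", RRNA)):
        cat = concat(ftype)
        if cat:
            report[key] = base_composition(cat)
        else:
            warnings.warn(f"no {ftype} features; {key} row omitted", stacklevel=2)

    cr = genome.features_of_type(CONTROL_REGION)
    if cr:
        report["AT-rich"] = base_composition(
            extract_feature_sequence(genome, cr[0].name)
        )
    else:
        warnings.warn("no control region; AT-rich row omitted", stacklevel=2)
    return report


def report_to_frame(report: dict[str, Composition], rounded: bool = True) -> pd.DataFrame:
    """Regional report as a DataFrame in the standard column order."""
    rows = {}
    for region, comp in report.items():
        c = comp.rounded() if rounded else comp
        rows[region] = [
            c.a_pct, c.t_pct, c.g_pct, c.c_pct,
            c.at_pct, c.at_skew, c.gc_skew, c.length,
        ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(REPORT_COLUMNS))
    df.index.name = "Region"
    return df
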