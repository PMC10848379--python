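"""Codon counting, CDspT and relative synonymous codon usage (RSCU).

RSCU of a codon c in synonymous family F is

    RSCU(c) = count(c) * |F| / sum(count(c') for c' in F)

so an unbiased family has RSCU 1 everywhere and single-codon families are
identically 1.  CDspT (codons per thousand) is count(c) * 1000 / total.

Two codon-family conventions are provided.  The "as-published" map groups
codons as mitogenome codon-usage tables conventionally print them: the
standard genetic code with leucine split into UUR and CUN, serine into
UCN and AGY, arginine into CGN and AGR, and the three terminators as one
family.  The invertebrate-mitochondrial map (translation table 5) moves
AUA to Met, UGA to Trp and AGR to Ser.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .composition import round_half_up
from .genome_model import AnnotatedGenome, extract_feature_sequence
from .vocab import PCG

logger = logging.getLogger(__name__)

BASES = "UCAG"
ALL_CODONS = tuple("".join(p) for p in itertools.product(BASES, repeat=3))


@dataclass
class CodonCountTable:
    """Per-codon counts (RNA alphabet) over a set of coding genes."""

    counts: dict[str, int]
    source_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(ALL_CODONS)
        if bad:
            raise ValueError(f"not codons: {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative codon count")

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)


@dataclass(frozen=True)
class CodonFamily:
    """One synonymous group: its codons and amino-acid label ('*' = stop)."""

    codons: tuple[str, ...]
    label: str


@dataclass
class CodonFamilyMap:
    """Disjoint partition of (a subset of) the 64 codons into families."""

    families: list[CodonFamily]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fam in self.families:
            dup = seen & set(fam.codons)
            if dup:
                raise ValueError(f"codon in two families: {sorted(dup)}")
            seen.update(fam.codons)

    def family_of(self, codon: str) -> CodonFamily | None:
        for fam in self.families:
            if codon in fam.codons:
                return fam
        return None

    @property
    def covered(self) -> set[str]:
        return {c for fam in self.families for c in fam.codons}


@dataclass
class RscuTable:
    """RSCU and CDspT per codon; codons in zero-total families are absent."""

    rscu: dict[str, float]
    cdspt: dict[str, float]


def _quartet(prefix: str) -> tuple[str, ...]:
    return tuple(prefix + b for b in BASES)


def family_map_as_published() -> CodonFamilyMap:
    """Standard-code grouping as printed in mitogenome codon-usage tables."""
    fams = [
        CodonFamily(("UUU", "UUC"), "F"),
        CodonFamily(("UUA", "UUG"), "L"),
        CodonFamily(_quartet("CU"), "L"),
        CodonFamily(("AUU", "AUC", "AUA"), "I"),
        CodonFamily(("AUG",), "M"),
        CodonFamily(_quartet("GU"), "V"),
        CodonFamily(_quartet("UC"), "S"),
        CodonFamily(_quartet("CC"), "P"),
        CodonFamily(_quartet("AC"), "T"),
        CodonFamily(_quartet("GC"), "A"),
        CodonFamily(("UAU", "UAC"), "Y"),
        CodonFamily(("UAA", "UAG", "UGA"), "*"),
        CodonFamily(("CAU", "CAC"), "H"),
        CodonFamily(("CAA", "CAG"), "Q"),
        CodonFamily(("AAU", "AAC"), "N"),
        CodonFamily(("AAA", "AAG"), "K"),
        CodonFamily(("GAU", "GAC"), "D"),
        CodonFamily(("GAA", "GAG"), "E"),
        CodonFamily(("UGU", "UGC"), "C"),
        CodonFamily(("UGG",), "W"),
        CodonFamily(_quartet("CG"), "R"),
        CodonFamily(("AGA", "AGG"), "R"),
        CodonFamily(("AGU", "AGC"), "S"),
        CodonFamily(_quartet("GG"), "G"),
    ]
    return CodonFamilyMap(fams)


def family_map_invertebrate_mito() -> CodonFamilyMap:
    """Invertebrate mitochondrial code (table 5) grouping."""
    fams = [
        CodonFamily(("UUU", "UUC"), "F"),
        CodonFamily(("UUA", "UUG"), "L"),
        CodonFamily(_quartet("CU"), "L"),
        CodonFamily(("AUU", "AUC"), "I"),
        CodonFamily(("AUG", "AUA"), "M"),
        CodonFamily(_quartet("GU"), "V"),
        CodonFamily(_quartet("UC"), "S"),
        CodonFamily(("AGU", "AGC", "AGA", "AGG"), "S"),
        CodonFamily(_quartet("CC"), "P"),
        CodonFamily(_quartet("AC"), "T"),
        CodonFamily(_quartet("GC"), "A"),
        CodonFamily(("UAU", "UAC"), "Y"),
        CodonFamily(("UAA", "UAG"), "*"),
        CodonFamily(("CAU", "CAC"), "H"),
        CodonFamily(("CAA", "CAG"), "Q"),
        CodonFamily(("AAU", "AAC"), "N"),
        CodonFamily(("AAA", "AAG"), "K"),
        CodonFamily(("GAU", "GAC"), "D"),
        CodonFamily(("GAA", "GAG"), "E"),
        CodonFamily(("UGU", "UGC"), "C"),
        CodonFamily(("UGG", "UGA"), "W"),
        CodonFamily(_quartet("CG"), "R"),
        CodonFamily(_quartet("GG"), "G"),
    ]
    return CodonFamilyMap(fams)


def family_map_for_code(code: str | int) -> CodonFamilyMap:
    """Look up a family map: 'published' (std grouping) or 5/'mito5'."""
    if code in ("published", "standard", 1):
        return family_map_as_published()
    if code in ("mito5", "invertebrate", 5):
        return family_map_invertebrate_mito()
    raise ValueError(f"unknown genetic-code mode: {code!r}")


def count_codon_string(seq: str) -> dict[str, int]:
    """Count consecutive non-overlapping triplets of a sense-strand CDS.

    A trailing 1–2 nt partial codon (incomplete stop) is dropped and
    logged.  DNA T is transcribed to RNA U in the returned keys.
    """
    rna = seq.upper().replace("T", "U")
    tail = len(rna) % 3
    if tail:
        logger.info("dropping %d trailing nt (incomplete terminal codon)", tail)
        rna = rna[: len(rna) - tail]
    counts: dict[str, int] = {}
    for i in range(0, len(rna), 3):
        codon = rna[i:i + 3]
        if codon not in _CODON_SET:
            raise ValueError(f"ambiguous codon {codon!r} at nt {i + 1}")
        counts[codon] = counts.get(codon, 0) + 1
    return counts


_CODON_SET = set(ALL_CODONS)


def count_codons(genome: AnnotatedGenome, genes: list[str] | None = None) -> CodonCountTable:
    """Codon counts over the listed protein-coding genes (default: all 13)."""
    if genes is None:
        feats = genome.features_of_type(PCG)
    else:
        feats = [genome.feature(g) for g in genes]
    counts: dict[str, int] = {}
    used: list[str] = []
    for f in feats:
        if f.type != PCG:
            raise ValueError(f"not a coding feature: {f.name}")
        for codon, n in count_codon_string(
            extract_feature_sequence(genome, f.name)
        ).items():
            counts[codon] = counts.get(codon, 0) + n
        used.append(f.name)
    return CodonCountTable(counts=counts, source_genes=used)


def rscu(counts: CodonCountTable, fam: CodonFamilyMap) -> RscuTable:
    """RSCU and CDspT from a count table under a family map.

    Codons with nonzero count outside the family map are reported (warn
    level) and skipped; families whose total count is zero yield no RSCU
    entries (undefined, not zero).
    """
    uncovered = {c for c, n in counts.counts.items() if n > 0} - fam.covered
    if uncovered:
        logger.warning("codons outside the family map: %s", sorted(uncovered))
    table: dict[str, float] = {}
    for family in fam.families:
        total = sum(counts.get(c) for c in family.codons)
        if total == 0:
            continue
        size = len(family.codons)
        for c in family.codons:
            table[c] = counts.get(c) * size / total
    total_codons = counts.total_codons
    cdspt = {
        c: 1000 * n / total_codons
        for c, n in counts.counts.items()
        if total_codons
    }
    return RscuTable(rscu=table, cdspt=cdspt)


def amino_acid_usage(counts: CodonCountTable, fam: CodonFamilyMap) -> dict[str, int]:
    """Total codon count per amino-acid label (split families merged)."""
    usage: dict[str, int] = {}
    for family in fam.families:
        n = sum(counts.get(c) for c in family.codons)
        usage[family.label] = usage.get(family.label, 0) + n
    return usage


def rscu_rounded(table: RscuTable, ndigits: int = 3) -> dict[str, float]:
    """RSCU values rounded half-up for printed-table parity."""
    return {c: round_half_up(v, ndigits) for c, v in table.rscu.items()}
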