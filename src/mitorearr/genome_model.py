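"""Core data types for annotated circular mitochondrial genomes.

Coordinates are 1-based, fully closed intervals, as printed in mitogenome
annotation tables.  The circle's origin sits between position ``length``
and position 1; a feature that spans the origin carries an explicit
``wraps`` flag rather than being inferred from ``start > end`` alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from . import vocab
from .vocab import CONTROL_REGION, PCG, RRNA, TRNA, normalize_label

logger = logging.getLogger(__name__)

_IUPAC = set("ACGTURYSWKMBDHVN")

FEATURE_TABLE_COLUMNS = ("gene", "type", "start", "end", "strand", "anticodon")


class AlphabetError(ValueError):
    """Sequence contains a character outside the IUPAC nucleotide codes."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the circular genome.

    ``start``/``end`` are 1-based inclusive.  ``wraps`` marks an
    origin-spanning feature (its arc runs start..L then 1..end).
    """

    name: str
    type: str
    start: int
    end: int
    strand: str  # "H" (heavy) or "L" (light)
    anticodon: Optional[str] = None
    amino_acids: Optional[int] = None
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.type not in vocab.FEATURE_TYPES:
            raise ValueError(f"unknown feature type: {self.type!r}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError("coordinates are 1-based; start/end must be >= 1")
        if not self.wraps and self.end < self.start:
            raise ValueError(
                f"{self.name}: end < start without wrap flag "
                "(origin-spanning features must set wraps=True)"
            )

    def length(self, genome_length: Optional[int] = None) -> int:
        """Feature length in bp (requires *genome_length* when wrapping)."""
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError("genome_length required for a wrapping feature")
        return (genome_length - self.start + 1) + self.end

    def intervals(self, genome_length: int) -> list[tuple[int, int]]:
        """Linear (start, end) pieces covering the feature's circular arc."""
        if self.wraps:
            return [(self.start, genome_length), (1, self.end)]
        return [(self.start, self.end)]


@dataclass
class AnnotatedGenome:
    """Circular sequence plus ordered feature set.

    ``seq`` may be empty for an annotation-only skeleton, in which case
    ``declared_length`` carries the genome size.
    """

    seq: str = ""
    features: list[GeneFeature] = field(default_factory=list)
    name: str = "genome"
    genetic_code_id: int = 5  # invertebrate mitochondrial
    declared_length: Optional[int] = None

    @property
    def length(self) -> int:
        if self.seq:
            return len(self.seq)
        if self.declared_length is not None:
            return self.declared_length
        if self.features:
            return max(f.end for f in self.features)
        raise ValueError("genome has neither sequence nor declared length")

    @property
    def has_sequence(self) -> bool:
        return bool(self.seq)

    def feature(self, name: str) -> GeneFeature:
        label = normalize_label(name)
        for f in self.features:
            if f.name == label:
                return f
        raise KeyError(f"feature not found: {name!r}")

    def features_of_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.type == ftype]

    def type_tally(self) -> dict[str, int]:
        """Feature count per type (e.g. 13 PCG + 22 tRNA + 2 rRNA + 1 CR)."""
        tally = {t: 0 for t in vocab.FEATURE_TYPES}
        for f in self.features:
            tally[f.type] += 1
        return tally

    def validate(self) -> None:
        if not self.features and not self.seq and self.declared_length is None:
            return  # empty skeleton is trivially valid
        L = self.length
        seen: set[str] = set()
        for f in self.features:
            if f.name in seen:
                raise ValueError(f"duplicate feature: {f.name}")
            seen.add(f.name)
            if f.start > L or f.end > L:
                raise ValueError(
                    f"{f.name}: coordinate out of range (genome length {L})"
                )


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read the first record of a FASTA file.

    Returns ``(record_id, sequence)`` with the sequence upper-cased and
    restricted to IUPAC nucleotide codes.  Extra records are ignored with
    a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequence in {path}")
    if len(records) > 1:
        logger.warning(
            "%s contains %d records; using the first (%s)",
            path, len(records), records[0].id,
        )
        warnings.warn(f"{path}: multiple records, using the first", stacklevel=2)
    rec = records[0]
    seq = str(rec.seq).upper()
    for i, ch in enumerate(seq, start=1):
        if ch not in _IUPAC:
            raise AlphabetError(
                f"invalid alphabet: {ch!r} at position {i} of record {rec.id}"
            )
    return rec.id, seq


def read_feature_table(
    path: str | Path,
    genome_length: Optional[int] = None,
) -> AnnotatedGenome:
    """Read a TSV feature table into an annotation-only genome skeleton.

    Expected header: ``gene type start end strand anticodon`` (anticodon
    optional).  An optional comment line ``# genome_length: N`` declares
    the circle size; an explicit *genome_length* argument overrides it.
    Gene names are folded to the canonical vocabulary and features are
    sorted by start coordinate.
    """
    path = Path(path)
    declared = genome_length
    with open(path) as fh:
        head = fh.readline()
        while head.startswith("#"):
            if "genome_length" in head and declared is None:
                declared = int(head.split(":")[1].strip())
            head = fh.readline()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = {"gene", "type", "start", "end", "strand"} - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")

    feats: list[GeneFeature] = []
    names: set[str] = set()
    for row in df.itertuples(index=False):
        label = normalize_label(row.gene)
        if label in names:
            raise ValueError(f"duplicate feature: {label}")
        names.add(label)
        ftype = _normalize_type(str(row.type))
        anticodon = getattr(row, "anticodon", None)
        if pd.isna(anticodon) or anticodon == "":
            anticodon = None
        wraps = False
        if "wraps" in df.columns:
            wraps = str(getattr(row, "wraps", "")).strip().lower() in ("1", "true", "yes")
        feats.append(
            GeneFeature(
                name=label,
                type=ftype,
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand).strip(),
                anticodon=anticodon,
                wraps=wraps,
            )
        )
    feats.sort(key=lambda f: (f.start, -(f.end - f.start)))
    genome = AnnotatedGenome(
        features=feats, name=path.stem, declared_length=declared
    )
    genome.validate()
    return genome


def _normalize_type(raw: str) -> str:
    key = raw.strip().lower().replace("-", "_").replace(" ", "_")
    table = {
        "pcg": PCG, "cds": PCG, "protein": PCG,
        "trna": TRNA, "rrna": RRNA,
        "control_region": CONTROL_REGION, "cr": CONTROL_REGION,
        "at_rich": CONTROL_REGION, "d_loop": CONTROL_REGION,
    }
    try:
        return table[key]
    except KeyError:
        raise ValueError(f"unknown feature type: {raw!r}") from None


def write_feature_table(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write the annotation as a TSV round-trippable by read_feature_table."""
    rows = []
    any_wrap = any(f.wraps for f in genome.features)
    for f in sorted(genome.features, key=lambda f: (f.start, -(f.end - f.start))):
        row = {
            "gene": f.name,
            "type": f.type,
            "start": f.start,
            "end": f.end,
            "strand": f.strand,
            "anticodon": f.anticodon or "",
        }
        if any_wrap:
            row["wraps"] = "1" if f.wraps else "0"
        rows.append(row)
    cols = list(FEATURE_TABLE_COLUMNS) + (["wraps"] if any_wrap else [])
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w", newline="\n") as fh:
        try:
            fh.write(f"# genome_length: {genome.length}\n")
        except ValueError:
            pass
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_feature_sequence(genome: AnnotatedGenome, name: str) -> str:
    """Sense-strand (5'→3' coding) sequence of the named feature.

    Light-strand features are reverse-complemented; origin-spanning
    features are stitched across the origin before orientation.
    """
    if not genome.has_sequence:
        raise ValueError("sequence not loaded")
    f = genome.feature(name)
    if f.wraps:
        raw = genome.seq[f.start - 1:] + genome.seq[: f.end]
    else:
        raw = genome.seq[f.start - 1: f.end]
    return reverse_complement(raw) if f.strand == "L" else raw


def to_gene_order(genome: AnnotatedGenome, include_cr: bool = True):
    """Signed circular gene order of the annotation.

    Features are ordered by start coordinate (ties: longer feature first,
    with a warning); light-strand features carry a negative sign.  The
    control region participates as an orderable token unless excluded.
    """
    from .gene_order import GeneOrder  # local import to avoid a cycle

    feats = sorted(genome.features, key=lambda f: (f.start, -(f.end - f.start)))
    starts = [f.start for f in feats]
    if len(set(starts)) != len(starts):
        warnings.warn(
            "features with identical starts; ties broken longest-first",
            stacklevel=2,
        )
    tokens = [
        (f.name, +1 if f.strand == "H" else -1)
        for f in feats
        if include_cr or f.type != CONTROL_REGION
    ]
    return GeneOrder(tokens=tuple(tokens), species=genome.name)
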