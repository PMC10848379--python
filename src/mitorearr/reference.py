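"""Packaged reference data for the porcelain-crab mitogenome study system.

Ships the published annotation table (gene coordinates, strands,
anticodons; genome length 15,344 bp), the published regional composition
percentages, the published codon-count/RSCU table over the 13 PCGs, the
pancrustacean ground-pattern gene order, and the inferred
TDRL+translocation rearrangement history between the two orders.

Tables are stored verbatim as printed, including their known internal
inconsistencies (e.g. nad5 length 1713 by coordinates vs 1680 in the
composition table); downstream code recomputes derived quantities from
the raw cells rather than trusting printed summaries.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .gene_order import GeneOrder, parse_order, read_order_file
from .genome_model import AnnotatedGenome, read_feature_table, to_gene_order
from .rearrangement import RearrangementOp, RearrangementScenario


def _data_path(name: str):
    return resources.files("mitorearr.data").joinpath(name)


def load_annotation() -> AnnotatedGenome:
    """The published 38-feature annotation (13 PCG + 22 tRNA + 2 rRNA + CR)."""
    with resources.as_file(_data_path("pisidia_features.tsv")) as p:
        genome = read_feature_table(p)
    genome.name = "Pisidia_serratifrons"
    return genome


def load_composition_table() -> pd.DataFrame:
    """Published regional composition percentages, indexed by region."""
    with resources.as_file(_data_path("pisidia_composition.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="region")


def load_codon_counts() -> pd.DataFrame:
    """Published per-codon counts and printed RSCU over the 13 PCGs."""
    with resources.as_file(_data_path("pisidia_codon_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="codon")


def ground_pattern_order() -> GeneOrder:
    """The pancrustacean ancestral gene order (signed, CR included)."""
    with resources.as_file(_data_path("pancrustacean_order.txt")) as p:
        return read_order_file(p)[0]


def observed_order() -> GeneOrder:
    """The observed gene order, derived from the annotation coordinates."""
    return to_gene_order(load_annotation())


def published_scenario() -> RearrangementScenario:
    """The inferred rearrangement history (2 TDRL events + 4 translocations)."""
    with resources.as_file(_data_path("pisidia_scenario.json")) as p:
        d = json.loads(p.read_text())
    return RearrangementScenario(
        ops=[RearrangementOp.from_json(o) for o in d["ops"]],
        source=parse_order(d["source"], species="ground_pattern"),
        target=parse_order(d["target"], species="Pisidia_serratifrons"),
    )


#: base counts of the deposited 15,344 bp genome, reconstructed from the
#: published percentages (A 37.78 / T 36.51 / G 9.70 / C 16.01)
PUBLISHED_GENOME_BASE_COUNTS = {"A": 5797, "C": 2457, "G": 1488, "T": 5602}
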