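#!/usr/bin/env python
"""Codon usage: RSCU and CDspT over the 13 protein-coding genes.

Recomputes RSCU from the packaged per-codon counts under the
as-published family grouping, compares with the printed values, and
totals amino-acid usage.  Writes results/rscu.tsv.
"""

from pathlib import Path

import pandas as pd

from mitorearr import reference
from mitorearr.codon_usage import (
    CodonCountTable,
    amino_acid_usage,
    family_map_as_published,
    rscu,
    rscu_rounded,
)
from mitorearr.composition import round_half_up

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = reference.load_codon_counts()
    counts = CodonCountTable(counts={c: int(n) for c, n in table["count"].items()})
    fam = family_map_as_published()
    out = rscu(counts, fam)
    rounded = rscu_rounded(out)

    rows = []
    for codon in table.index:
        printed = float(table.loc[codon, "rscu_printed"])
        rows.append(
            {
                "codon": codon,
                "family": fam.family_of(codon).label,
                "count": int(table.loc[codon, "count"]),
                "cdspt": round_half_up(out.cdspt.get(codon, 0.0), 3),
                "rscu": rounded[codon],
                "rscu_printed": printed,
                "match": abs(rounded[codon] - printed) <= 5e-4,
            }
        )
    df = pd.DataFrame(rows).set_index("codon")
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "rscu.tsv", sep="\t", lineterminator="\n")

    usage = amino_acid_usage(counts, fam)
    top = max((k for k in usage if k != "*"), key=lambda k: usage[k])
    n_match = int(df["match"].sum())
    print(f"wrote {OUT / 'rscu.tsv'} ({counts.total_codons} codons)")
    print(f"{n_match}/{len(df)} printed RSCU values reproduced to 3 dp "
          f"(mismatches: {sorted(df.index[~df['match']])})")
    print(f"most-used amino acid: {top} ({usage[top]} codons)")


if __name__ == "__main__":
    main()
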