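#!/usr/bin/env python
"""Overlaps and intergenic spacers of the circular annotation.

Computes all pairwise gene overlaps and rank-adjacent spacers from the
packaged annotation coordinates.  Writes results/geometry.json.
"""

import json
from pathlib import Path

from mitorearr import reference
from mitorearr.annotation_geometry import geometry_summary

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    genome = reference.load_annotation()
    rep = geometry_summary(genome)
    payload = {
        "overlaps": [list(x) for x in rep.overlaps],
        "spacers": [list(x) for x in rep.spacers],
        "totals": rep.totals,
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "geometry.json").write_text(json.dumps(payload, indent=2) + "\n")

    t = rep.totals
    gaps = {a: g for a, _, g in rep.spacers}
    print(f"wrote {OUT / 'geometry.json'}")
    print(f"{t['overlap_count']} overlapping gene pairs "
          f"(max {t['spacer_max_bp'] and max(o for *_, o in rep.overlaps)} bp); "
          f"{t['spacer_count']} spacers totalling {t['spacer_total_bp']} bp")
    print(f"largest spacer: {t['spacer_max_bp']} bp after trnI "
          f"(45 bp after trnT: {gaps.get('trnT') == 45})")


if __name__ == "__main__":
    main()
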