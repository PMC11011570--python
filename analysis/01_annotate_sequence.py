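#!/usr/bin/env python
"""Annotate a synthetic hydrogenase-like candidate sequence.

Builds a 549-residue sequence with the divergent P1 core (ASACPGW) at
position 223 and the four F-cluster cysteines at 21/72/75/78, then runs
the fingerprint scan, the Cys-spacing detector, and the domain
segmentation, writing a JSON report to results/.
"""

import json
from pathlib import Path

from metallotraj import (MotifDef, DEFAULT_MOTIFS, scan_motifs,
                         find_cys_positions, detect_cys_pattern,
                         segment_domains, gen_sequence)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

P1 = MotifDef("P1", DEFAULT_MOTIFS["P1"], max_mismatches=2,
              anchored_positions=frozenset({4}))
VARIANT = MotifDef("P1", "ASACPGW", max_mismatches=0)

sequence, truth = gen_sequence(
    549,
    planted_motifs=[(VARIANT, 223)],
    planted_cys_positions=[21, 72, 75, 78],
    seed=20240301,
)

hits = scan_motifs(sequence, [P1])
cys = find_cys_positions(sequence)
f_cluster_cys = [p for p in cys if p <= 88]
pattern = detect_cys_pattern(f_cluster_cys)
domains = segment_domains(sequence, hits)

report = {
    "length": len(sequence),
    "p1_hits": [{"start": h.start, "matched": h.matched,
                 "mismatch_offsets": list(h.mismatch_positions)}
                for h in hits],
    "cys_positions": cys,
    "f_cluster_cys_pattern": pattern.spacer_string,
    "domains": {k: list(v) for k, v in domains.ranges.items()},
}
(OUT / "annotation.json").write_text(json.dumps(report, indent=2) + "\n")
print(json.dumps(report, indent=2))
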