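#!/usr/bin/env python
"""Survey statistics of the packaged 294-gene family catalog: type
counts, chromosome distribution, exon histogram, bHLH cross-tab and
family shares.

Writes results/catalog_summary.json.
"""
import json
from pathlib import Path

from mybkit.catalog import catalog_summary, family_share
from mybkit.data import load_table1_catalog

ROOT = Path(__file__).resolve().parents[1] / "results"
ROOT.mkdir(exist_ok=True)
entries = load_table1_catalog()
summary = catalog_summary(entries)
summary["family_share_protein_coding_percent"] = family_share(
    summary["type_counts"]["R2R3"], 35276, 2
)
summary["family_share_tf_percent"] = family_share(
    summary["type_counts"]["R2R3"], 3155, 1
)
(ROOT / "catalog_summary.json").write_text(json.dumps(summary, indent=1))
t = summary["type_counts"]
h = summary["r2r3_exon_histogram"]
print(f"{summary['n_total']} genes: {t['R2R3']} R2R3 + {t['3R']} 3R + "
      f"{t['4R']} 4R + {t['CDC5']} CDC5; {summary['n_placed']} placed, "
      f"{summary['n_unplaced']} unplaced; "
      f"3-exon mode {h['3']['count']} ({h['3']['percent']}%); "
      f"{summary['n_bhlh']} bHLH-motif genes; family share "
      f"{summary['family_share_protein_coding_percent']}% of protein-coding, "
      f"{summary['family_share_tf_percent']}% of TF genes "
      f"-> results/catalog_summary.json")
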