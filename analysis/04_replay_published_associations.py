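"""Summarise the published rSNP-gene-GWAS association table.

Feeds the packaged table of reported regulatory SNPs at GWAS-implicated
loci for cognition-related traits through the report summariser,
reproducing the headline unique counts (14 regulatory SNPs targeting 12
genes).  Writes results/04_published_replay.json.
"""

import json
from pathlib import Path

from regsnp_scout.gwas_linkage import (load_published_associations,
                                       summarize_report)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = load_published_associations()
    summary = summarize_report(rows)
    per_trait = rows.groupby("trait").display_id.nunique().to_dict()
    out = {"summary": summary, "unique_rsnps_per_trait": per_trait}
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with open(results / "04_published_replay.json", "w") as fh:
        json.dump(out, fh, indent=1)
    print(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
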