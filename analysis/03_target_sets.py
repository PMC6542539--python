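#!/usr/bin/env python
"""IQR-outlier target sets and their exclusive/shared structure.

Calls targets per strain with the boxplot rule (corrected efficiency
above Q3 + 1.5 IQR), removes genes that outlie in the untagged control,
and reports exclusive targets and Venn-region sizes across strains --
the analysis behind "bound exclusively by" and "shared targets of"
statements about synthetase pairs.
"""

import json
from pathlib import Path

import pandas as pd

from ripscan.io import write_json
from ripscan.targets import (
    TargetCallParams,
    call_targets,
    exclusive_targets,
    shared_targets,
    untagged_outliers,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    truth = json.loads((RESULTS / "data" / "truth.json").read_text())["truth"]
    params = TargetCallParams(k=1.5, center_rule="quartile")
    sets = {}
    for strain in truth:
        tab = pd.read_csv(
            RESULTS / f"enrichment_{strain}.tsv", sep="\t", index_col="gene_id"
        )
        ts = call_targets(tab["corrected"], params, label=strain)
        drop = untagged_outliers(tab["untagged_efficiency"].dropna(), params)
        ts = type(ts)(
            label=strain, members=ts.members - drop,
            threshold=ts.threshold, params=params,
        )
        sets[strain] = ts
        planted_ids = {f"gene{g:05d}" for g, _ in truth[strain]}
        print(
            f"{strain}: {len(ts.members)} targets called "
            f"(threshold {ts.threshold:.2f}); "
            f"{len(planted_ids & ts.members)}/{len(planted_ids)} planted recovered"
        )

    exclusive = exclusive_targets(sets)
    regions = shared_targets(sets)
    summary = {
        "per_strain": {s: sorted(ts.members) for s, ts in sets.items()},
        "exclusive": {s: sorted(g) for s, g in exclusive.items()},
        "venn_regions": {
            "+".join(sorted(k)): sorted(v) for k, v in regions.items()
        },
    }
    write_json(summary, RESULTS / "target_sets.json")
    for pattern, genes in sorted(summary["venn_regions"].items()):
        if genes:
            print(f"  region {pattern}: {len(genes)} gene(s)")
    print(f"-> {RESULTS/'target_sets.json'}")


if __name__ == "__main__":
    main()
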