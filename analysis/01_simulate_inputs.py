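#!/usr/bin/env python
"""Generate the synthetic study inputs for the downstream analyses.

Simulates RIP-seq count tables for three TAP-tagged synthetase strains
(each with its untagged control), one tiling-fragment fRIP panel, and a
coding sequence carrying a designed GUG anticodon-mimic stem-loop.
Planted targets overlap across strains so the exclusive/shared set
analysis has structure to find.  All outputs land in results/data/.
"""

from pathlib import Path

from ripscan.io import write_count_table, write_fasta, write_json
from ripscan.synthetic import (
    FripSimParams,
    RipSimParams,
    simulate_cds_with_mimic,
    simulate_frip,
    simulate_ripseq,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 3000274

# Planted target structure: every strain binds its own mRNA (distinct
# "self" gene), plus shared and exclusive targets.
PLANTED = {
    "GluRS": ((5, 25.0), (7, 15.0), (8, 12.0), (12, 10.0), (20, 10.0)),
    "HisRS": ((6, 40.0), (7, 15.0), (8, 12.0), (31, 10.0)),
    "MetRS": ((9, 20.0), (8, 12.0), (44, 10.0)),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truths = {}
    for i, (strain, planted) in enumerate(PLANTED.items()):
        params = RipSimParams(
            n_genes=2000,
            lib_size_input=2_000_000,
            lib_size_bound=2_000_000,
            dispersion=0.1,
            planted=planted,
            strain=strain,
            seed=SEED + i,
        )
        table, truth = simulate_ripseq(params)
        path = OUT / f"counts_{strain}.tsv"
        write_count_table(table, path)
        truths[strain] = [[int(g), float(f)] for g, f in truth.planted]
        print(f"{strain}: {params.n_genes} genes, planted {truths[strain]} -> {path}")

    panel = simulate_frip(FripSimParams(site_fragment=10, carryover=0.4, seed=SEED))
    panel.to_csv(OUT / "frip_panel.tsv", sep="\t")
    print(f"fRIP panel: site fragment 10 of 14 -> {OUT/'frip_panel.tsv'}")

    cds, pos = simulate_cds_with_mimic(
        1644, "GUG", insert_pos=1101, stem_len=5, seed=SEED
    )
    write_fasta({"synthetic_mimic_cds": cds}, OUT / "mimic_cds.fa")
    write_json({"truth": truths, "mimic_triplet_pos": pos, "seed": SEED},
               OUT / "truth.json")
    print(f"mimic CDS: 1,644 nt, GUG loop at nt {pos} -> {OUT/'mimic_cds.fa'}")


if __name__ == "__main__":
    main()
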