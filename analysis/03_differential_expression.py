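#!/usr/bin/env python
"""Per-organ two-factor contrasts, DEG calls, and the partition tables.

For each organ: a 2×2 genotype × condition cell-means ANOVA per probe,
pooled-variance t contrasts (drought vs control within each genotype at
FC ≥ 3; tolerant vs sensitive within control at FC ≥ 2), BH-FDR at
q ≤ 0.05, and probe→gene collapse. DEG universes are then partitioned by
genotype exclusivity within organs and by organ across them.
"""

import json
from pathlib import Path

from droughtprime import io as dio
from droughtprime.pipeline import run_core

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    raw = dio.read_expression(BASE / "data" / "expression.tsv")
    samples = dio.read_sample_sheet(BASE / "data" / "samples.tsv", raw)
    probe_map = dio.read_probe_map(BASE / "data" / "probe_map.tsv")

    bundle = run_core(raw, samples, probe_map)
    out = BASE / "deg"
    out.mkdir(parents=True, exist_ok=True)
    for name, table in bundle.probe_tables.items():
        table.to_csv(out / f"probes_{name}.tsv", sep="\t")
    for name, table in bundle.gene_tables.items():
        table.to_csv(out / f"genes_{name}.tsv", sep="\t")

    counts = {
        organ: bundle.partitions[organ]["counts"] for organ in ("root", "leaf")
    }
    counts["organ"] = bundle.partitions["organ"]["counts"]
    (out / "partition_counts.json").write_text(json.dumps(counts, indent=2) + "\n")

    for organ in ("root", "leaf"):
        c = counts[organ]
        print(
            f"{organ}: {c['tolerant_only']} tolerant-only + {c['sensitive_only']} "
            f"sensitive-only + {c['shared']} shared = {c['total']} drought DEGs"
        )
    oc = counts["organ"]
    print(
        f"across organs: {oc['root_exclusive']} root-exclusive, "
        f"{oc['leaf_exclusive']} leaf-exclusive, {oc['both']} in both"
    )


if __name__ == "__main__":
    main()
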