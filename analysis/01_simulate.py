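#!/usr/bin/env python
"""Generate the synthetic drought-transcriptome experiment.

Emulates the study design: 2 genotypes × 2 organs × 2 conditions × 3
replicate arrays, 1200 genes on 1–3 probes each, with planted drought
DEGs, priming candidates, initial-difference decoys, GO annotations with
designated enriched terms, and per-array scaling offsets. Writes the raw
matrix, sample sheet, probe map, annotations, ontology and truth labels
under results/data/.
"""

from pathlib import Path

from droughtprime import io as dio
from droughtprime.simulate import SimulationConfig, simulate_dataset, simulate_go_annotations

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    config = SimulationConfig(seed=SEED)
    raw, samples, probe_map, truth = simulate_dataset(config)
    annotations, dag, terms = simulate_go_annotations(truth, seed=SEED)

    OUT.mkdir(parents=True, exist_ok=True)
    dio.write_expression(raw, OUT / "expression.tsv")
    dio.write_sample_sheet(samples, OUT / "samples.tsv")
    dio.write_probe_map(probe_map, OUT / "probe_map.tsv")
    dio.write_annotations(annotations, OUT / "annotations.tsv")
    dio.write_obo(dag, OUT / "ontology.obo")
    terms.to_csv(OUT / "terms.tsv", sep="\t", index=False)
    dio.write_truth_labels(truth.labels_frame(), OUT / "truth_labels.tsv")

    planted = truth.planted["role"].value_counts()
    print(f"wrote {raw.shape[0]} probes × {raw.shape[1]} samples (seed {SEED})")
    print("planted genes by role:")
    print(planted.to_string())


if __name__ == "__main__":
    main()
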