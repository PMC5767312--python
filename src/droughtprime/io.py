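"""File formats: TSV tables, OBO ontologies, qPCR plates, run manifests.

Dialect: tab-separated, UTF-8, mandatory header row, "." decimal mark;
probe/gene identifiers are opaque strings. Every writer's output re-parses
under its own reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from droughtprime.enrichment import OntologyError, check_dag
from droughtprime.normalize import validate_sample_sheet


def read_expression(path: str | Path) -> pd.DataFrame:
    """Raw or normalized matrix: first column probe_id, remaining columns samples."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "probe_id"
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicate probe row {dup!r} in {path}")
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValueError(f"duplicate sample column {dup!r} in {path}")
    return matrix


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("probe_id").to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    validate_sample_sheet(samples, matrix)
    return samples


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "gene_id"):
        if col not in pm.columns:
            raise ValueError(f"probe map missing column {col!r}")
    if pm.duplicated().any():
        dup = pm[pm.duplicated()].iloc[0]
        raise ValueError(f"duplicate probe-map row ({dup['probe_id']}, {dup['gene_id']})")
    if pm["probe_id"].duplicated().any():
        dup = pm.loc[pm["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"probe {dup!r} maps to more than one gene")
    return pm


def write_probe_map(probe_map: pd.DataFrame, path: str | Path) -> None:
    probe_map.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GO


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Gene→terms from a two-column TSV (gene, term) or GAF 2.x lines
    (columns 2 and 5, '!' comments skipped)."""
    annotations: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        first = True
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) >= 15:  # GAF record
                gene, term = fields[1], fields[4]
            elif len(fields) >= 2:
                gene, term = fields[0], fields[1]
                if first and (gene.lower(), term.lower()) == ("gene", "term"):
                    first = False
                    continue
            else:
                raise ValueError(f"unparseable annotation line: {line!r}")
            first = False
            annotations.setdefault(gene, set()).add(term)
    return annotations


def write_annotations(annotations: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene\tterm\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                handle.write(f"{gene}\t{term}\n")


def read_obo(path: str | Path) -> nx.DiGraph:
    """Parse an OBO ontology (id/name/is_a/part_of) into a child→parent
    DiGraph; raises OntologyError on cycles."""
    multi = obonet.read_obo(str(path))
    dag = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        dag.add_node(node, name=data.get("name", ""))
    for child, parent, key in multi.edges(keys=True):
        if key in ("is_a", "part_of"):
            dag.add_edge(child, parent, relation=key)
    try:
        check_dag(dag)
    except OntologyError:
        raise
    return dag


def write_obo(dag: nx.DiGraph, path: str | Path, namespace: str = "biological_process") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("format-version: 1.2\nontology: go\n\n")
        for node in sorted(dag.nodes):
            handle.write("[Term]\n")
            handle.write(f"id: {node}\n")
            name = dag.nodes[node].get("name", node)
            handle.write(f"name: {name}\n")
            handle.write(f"namespace: {namespace}\n")
            for _, parent, data in dag.out_edges(node, data=True):
                rel = data.get("relation", "is_a")
                pname = dag.nodes[parent].get("name", parent)
                if rel == "is_a":
                    handle.write(f"is_a: {parent} ! {pname}\n")
                else:
                    handle.write(f"relationship: {rel} {parent} ! {pname}\n")
            handle.write("\n")


# ---------------------------------------------------------------------------
# qPCR


QPCR_COLUMNS = ("well", "amplicon", "sample", "condition", "replicate", "Ct")


def read_qpcr(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    plate = pd.read_csv(path, sep=sep)
    missing = [c for c in QPCR_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"qPCR table missing column(s): {missing}")
    return plate


def write_qpcr(plate: pd.DataFrame, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    plate.to_csv(path, sep=sep, index=False)


def read_qpcr_curves(path: str | Path) -> dict[str, pd.DataFrame]:
    """Long-format raw curves: columns well, cycle, fluorescence."""
    long = pd.read_csv(path, sep="\t")
    for col in ("well", "cycle", "fluorescence"):
        if col not in long.columns:
            raise ValueError(f"curve table missing column {col!r}")
    return {w: g.sort_values("cycle") for w, g in long.groupby("well")}


# ---------------------------------------------------------------------------
# truth labels, manifests


def write_truth_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def read_truth_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def file_checksum(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as handle:
        return json.load(handle)


# ---------------------------------------------------------------------------
# optional GEO loader (no tests depend on this; real data is never required)


def load_geo_series_matrix(path: str | Path) -> pd.DataFrame:
    """Minimal loader for a GEO series-matrix file already on disk
    (e.g. a download of GSE103278). Extracts only the expression table
    between the series_matrix_table markers."""
    rows = []
    header: list[str] | None = None
    in_table = False
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if in_table:
                fields = [f.strip('"') for f in line.split("\t")]
                if header is None:
                    header = fields
                else:
                    rows.append(fields)
    if header is None:
        raise ValueError(f"{path} contains no series-matrix table")
    table = pd.DataFrame(rows, columns=header).set_index(header[0])
    return table.apply(pd.to_numeric, errors="coerce")
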