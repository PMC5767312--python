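"""Per-organ two-factor differential-expression testing.

Within each organ the design is a balanced 2×2 (genotype × condition)
layout with replicates. The model is the cell-means parameterization of the
two-way ANOVA: each of the four (genotype, condition) cells gets its own
mean, the error variance is pooled across cells (MSE on N − 4 df), and the
biologically reported comparisons are pairwise contrasts of cell means
tested with pooled-variance t statistics:

* drought vs control within a genotype (the drought-response contrast,
  fold-change threshold FC ≥ 3), and
* tolerant vs sensitive within control (the initial-difference contrast,
  FC ≥ 2).

Raw p-values are adjusted per contrast with the Benjamini–Hochberg step-up
procedure; a probe is called differentially expressed when q ≤ α and
FC ≥ the contrast's threshold. Probe calls are collapsed to
high-confidence-gene calls through the probe→gene map (a gene passes in a
direction when at least one of its probes does).

Fold change is defined on the geometric-ratio scale, FC = 2^|Δ| where Δ is
the difference of mean log2 intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from droughtprime.normalize import CONDITIONS, GENOTYPES

# contrast kinds
DROUGHT_VS_CONTROL = "drought_vs_control_within_genotype"
TOLERANT_VS_SENSITIVE_CONTROL = "tolerant_vs_sensitive_within_control"

DEFAULT_ALPHA = 0.05
TAU_DROUGHT = 3.0  # linear fold-change threshold for drought contrasts
TAU_INIT = 2.0  # lowered stringency for the between-genotype control contrast


@dataclass(frozen=True)
class ContrastSpec:
    """A contrast to extract from the per-organ cell-means fit."""

    organ: str
    kind: str
    genotype: str | None = None  # required for drought contrasts
    fc_threshold: float = TAU_DROUGHT
    q_threshold: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError(f"fc_threshold must be ≥ 1, got {self.fc_threshold}")
        if not 0 < self.q_threshold < 1:
            raise ValueError(f"q_threshold must be in (0, 1), got {self.q_threshold}")
        if self.kind == DROUGHT_VS_CONTROL:
            if self.genotype not in GENOTYPES:
                raise ValueError(
                    f"drought contrast needs genotype in {GENOTYPES}, got {self.genotype!r}"
                )
        elif self.kind != TOLERANT_VS_SENSITIVE_CONTROL:
            raise ValueError(f"unknown contrast kind {self.kind!r}")

    @property
    def name(self) -> str:
        if self.kind == DROUGHT_VS_CONTROL:
            return f"{self.organ}_{self.genotype}_drought_vs_control"
        return f"{self.organ}_tolerant_vs_sensitive_control"


@dataclass
class CellMeansFit:
    """Per-probe 2×2 cell-means fit for one organ.

    means[probe, cell] holds arithmetic means of log2 values; cells are
    ordered per `cells` as (genotype, condition) pairs. MSE pools the
    within-cell sample variances; df = N_organ − 4.
    """

    organ: str
    probe_ids: pd.Index
    cells: list[tuple[str, str]]
    means: np.ndarray  # (n_probes, 4)
    mse: np.ndarray  # (n_probes,)
    df: int
    n_per_cell: dict[tuple[str, str], int] = field(default_factory=dict)

    def cell_index(self, genotype: str, condition: str) -> int:
        return self.cells.index((genotype, condition))


class DesignError(ValueError):
    """Raised when the within-organ design cannot support the pooled fit."""


def fit_cell_means(
    matrix: pd.DataFrame, samples: pd.DataFrame, organ: str
) -> CellMeansFit:
    """Fit the 2×2 cell-means model per probe within one organ.

    `samples` must be indexed by sample_id with genotype/organ/condition
    columns covering every matrix column used. Every (genotype, condition)
    cell needs ≥ 2 replicates so the pooled error variance is estimable.
    """
    organ_samples = samples[samples["organ"] == organ]
    cols = [c for c in matrix.columns if c in organ_samples.index]
    if not cols:
        raise DesignError(f"no samples for organ {organ!r}")
    sub = matrix[cols]
    cells = [(g, c) for g in GENOTYPES for c in CONDITIONS]
    groups: dict[tuple[str, str], list[str]] = {}
    for cell in cells:
        g, c = cell
        members = [
            s
            for s in cols
            if organ_samples.loc[s, "genotype"] == g
            and organ_samples.loc[s, "condition"] == c
        ]
        if len(members) < 2:
            raise DesignError(
                f"cell (genotype={g}, condition={c}) in organ {organ!r} has "
                f"{len(members)} replicate(s); need ≥ 2"
            )
        groups[cell] = members

    n_total = sum(len(v) for v in groups.values())
    means = np.empty((sub.shape[0], 4))
    ss_within = np.zeros(sub.shape[0])
    for k, cell in enumerate(cells):
        block = sub[groups[cell]].to_numpy(dtype=float)
        means[:, k] = block.mean(axis=1)
        ss_within += ((block - means[:, [k]]) ** 2).sum(axis=1)
    df = n_total - 4
    mse = ss_within / df
    return CellMeansFit(
        organ=organ,
        probe_ids=sub.index,
        cells=cells,
        means=means,
        mse=mse,
        df=df,
        n_per_cell={cell: len(v) for cell, v in groups.items()},
    )


def _contrast_cells(spec: ContrastSpec) -> tuple[tuple[str, str], tuple[str, str]]:
    """(positive cell, negative cell) so that delta = mean(pos) − mean(neg)."""
    if spec.kind == DROUGHT_VS_CONTROL:
        return (spec.genotype, "drought"), (spec.genotype, "control")
    return ("tolerant", "control"), ("sensitive", "control")


def contrast_test(fit: CellMeansFit, spec: ContrastSpec) -> pd.DataFrame:
    """Test one pairwise contrast of cell means for every probe.

    delta = difference of the two cell means; t = delta / sqrt(MSE·(1/n1 +
    1/n2)); two-sided p from the t distribution on the pooled df. Probes
    with MSE = 0 get the degenerate rule p = 1 if delta = 0 else p = 0, so
    noiseless fixtures stay testable.

    Returns a DataFrame indexed by probe with columns delta, FC, direction,
    p (q is attached by :func:`run_contrast` / :func:`bh_adjust`).
    """
    if spec.organ != fit.organ:
        raise ValueError(f"contrast organ {spec.organ!r} ≠ fit organ {fit.organ!r}")
    pos, neg = _contrast_cells(spec)
    delta = fit.means[:, fit.cell_index(*pos)] - fit.means[:, fit.cell_index(*neg)]
    n1, n2 = fit.n_per_cell[pos], fit.n_per_cell[neg]
    se = np.sqrt(fit.mse * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    p = np.where(
        se > 0,
        2.0 * stats.t.sf(np.abs(t), fit.df),
        np.where(delta == 0.0, 1.0, 0.0),
    )
    return pd.DataFrame(
        {
            "delta": delta,
            "FC": 2.0 ** np.abs(delta),
            "direction": np.where(delta >= 0, "up", "down"),
            "p": p,
        },
        index=fit.probe_ids.rename("probe_id"),
    )


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (q-values).

    q_(i) = min over j ≥ i of min(1, m·p_(j)/j) in sorted order; order-
    preserving and in [0, 1].
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return q


def call_probe_degs(stats_df: pd.DataFrame, spec: ContrastSpec) -> pd.DataFrame:
    """Flag probes passing both gates: q ≤ α and FC ≥ threshold (boundary
    values pass — both criteria are inclusive)."""
    if "q" not in stats_df.columns:
        raise ValueError("probe stats lack a 'q' column; run bh_adjust first")
    out = stats_df.copy()
    out["pass"] = (out["q"] <= spec.q_threshold) & (out["FC"] >= spec.fc_threshold)
    return out


def run_contrast(fit: CellMeansFit, spec: ContrastSpec) -> pd.DataFrame:
    """Convenience: contrast test → BH adjust → threshold calls."""
    stats_df = contrast_test(fit, spec)
    stats_df["q"] = bh_adjust(stats_df["p"].to_numpy())
    return call_probe_degs(stats_df, spec)


class MappingError(ValueError):
    """Raised when a probe maps to more than one gene."""


def collapse_probes_to_genes(
    probe_stats: pd.DataFrame, probe_map: pd.DataFrame
) -> pd.DataFrame:
    """Collapse probe-level calls to gene level.

    probe_map: columns (probe_id, gene_id); many probes per gene allowed,
    a probe must map to at most one gene. A gene passes in a direction iff
    ≥ 1 mapped probe passes in that direction; genes passing in both
    directions carry ``conflict``. The representative probe is the mapped
    probe with minimal q. Unmapped probes are simply absent from the output
    (their passing calls can be inspected at probe level).

    Returns a DataFrame indexed by gene_id with columns: pass_up,
    pass_down, passed (either), conflict, representative_probe, delta, FC,
    q (of the representative probe), direction.
    """
    if probe_map["probe_id"].duplicated().any():
        dup = probe_map.loc[probe_map["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise MappingError(f"probe {dup!r} maps to more than one gene")
    merged = probe_stats.merge(
        probe_map, left_index=True, right_on="probe_id", how="inner"
    )
    if merged.empty:
        return pd.DataFrame(
            columns=[
                "pass_up", "pass_down", "passed", "conflict",
                "representative_probe", "delta", "FC", "q", "direction",
            ]
        ).rename_axis("gene_id")

    merged["pass_up"] = merged["pass"] & (merged["direction"] == "up")
    merged["pass_down"] = merged["pass"] & (merged["direction"] == "down")
    rep = merged.loc[merged.groupby("gene_id")["q"].idxmin()].set_index("gene_id")
    flags = merged.groupby("gene_id")[["pass_up", "pass_down"]].any()
    out = flags.copy()
    out["passed"] = out["pass_up"] | out["pass_down"]
    out["conflict"] = out["pass_up"] & out["pass_down"]
    out["representative_probe"] = rep["probe_id"]
    for col in ("delta", "FC", "q", "direction"):
        out[col] = rep[col]
    return out.sort_index()


def deg_gene_sets(gene_stats: pd.DataFrame) -> dict[str, set[str]]:
    """Convenience sets from a collapsed gene table: all / up / down genes."""
    return {
        "all": set(gene_stats.index[gene_stats["passed"]]),
        "up": set(gene_stats.index[gene_stats["pass_up"]]),
        "down": set(gene_stats.index[gene_stats["pass_down"]]),
    }
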