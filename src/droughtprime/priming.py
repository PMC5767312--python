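"""Selection of "stressed-like readiness" (priming) candidate genes.

The priming hypothesis: a drought-tolerant genotype already holds, under
well-watered control conditions, the expression level that the sensitive
genotype only reaches after drought sets in. Operationally a gene is a
priming candidate in an organ when

1. it differs between genotypes under control conditions (initial
   contrast, FC ≥ τ_init = 2, q ≤ α), signed by which genotype is higher;
2. it responds to drought in the *sensitive* genotype (FC ≥ τ_drought = 3,
   q ≤ α); and
3. the directions agree: tolerant-initially-higher genes must be
   drought-up in the sensitive genotype (primed_high); tolerant-initially-
   lower genes must be drought-down (primed_low) — the sensitive genotype
   "catches up" to the tolerant baseline.

Being drought-DE in the tolerant genotype as well does not exclude a
candidate; that overlap is recorded as a flag and summarized separately.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

PRIMED_HIGH = "primed_high"
PRIMED_LOW = "primed_low"


@dataclass(frozen=True)
class PrimingCall:
    gene_id: str
    organ: str
    priming_direction: str  # primed_high | primed_low
    initial_fc: float
    initial_q: float
    sensitive_drought_fc: float
    sensitive_drought_q: float
    tolerant_drought_overlap: bool = False
    organ_class: str | None = None  # root_only | leaf_only | both
    cross_organ_discordant: bool = False

    def __post_init__(self) -> None:
        if self.priming_direction not in (PRIMED_HIGH, PRIMED_LOW):
            raise ValueError(f"bad priming_direction {self.priming_direction!r}")


def initial_difference_genes(
    control_contrast: pd.DataFrame, tau_init: float = 2.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Genes with an initial between-genotype difference under control.

    `control_contrast` is a collapsed gene table from the tolerant-vs-
    sensitive-within-control contrast (delta > 0 ⇒ tolerant higher).
    Returns the subset with FC ≥ tau_init and q ≤ alpha, with a
    ``tolerant_higher`` sign column.
    """
    required = {"FC", "q", "delta"}
    if not required <= set(control_contrast.columns):
        raise ValueError(
            f"expected a collapsed control-contrast table with columns {sorted(required)}"
        )
    passing = control_contrast[
        (control_contrast["FC"] >= tau_init) & (control_contrast["q"] <= alpha)
    ].copy()
    passing["tolerant_higher"] = passing["delta"] > 0
    return passing


def select_primed(
    initial: pd.DataFrame,
    sensitive_drought: pd.DataFrame,
    tolerant_drought: pd.DataFrame,
    organ: str,
    tau_drought: float = 3.0,
    alpha: float = 0.05,
    exclude_conflicts: bool = True,
) -> list[PrimingCall]:
    """Apply the three-part priming rule within one organ.

    initial:            output of :func:`initial_difference_genes`.
    sensitive_drought:  collapsed gene table for the sensitive genotype's
                        drought-vs-control contrast.
    tolerant_drought:   same for the tolerant genotype (used only for the
                        overlap flag, never as an exclusion filter).
    """
    calls: list[PrimingCall] = []
    tol_deg = set(tolerant_drought.index[tolerant_drought.get("passed", False)])
    for gene in initial.index:
        if exclude_conflicts and bool(initial.loc[gene].get("conflict", False)):
            continue
        if gene not in sensitive_drought.index:
            continue
        drow = sensitive_drought.loc[gene]
        if exclude_conflicts and bool(drow.get("conflict", False)):
            continue
        if not (drow["FC"] >= tau_drought and drow["q"] <= alpha and drow["passed"]):
            continue
        tolerant_higher = bool(initial.loc[gene, "tolerant_higher"])
        drought_up = drow["delta"] > 0
        if tolerant_higher and drought_up:
            direction = PRIMED_HIGH
        elif (not tolerant_higher) and (not drought_up):
            direction = PRIMED_LOW
        else:
            continue  # direction-inconsistent: not "following" the tolerant pattern
        calls.append(
            PrimingCall(
                gene_id=str(gene),
                organ=organ,
                priming_direction=direction,
                initial_fc=float(initial.loc[gene, "FC"]),
                initial_q=float(initial.loc[gene, "q"]),
                sensitive_drought_fc=float(drow["FC"]),
                sensitive_drought_q=float(drow["q"]),
                tolerant_drought_overlap=gene in tol_deg,
            )
        )
    return calls


def classify_priming_by_organ(
    root_calls: list[PrimingCall], leaf_calls: list[PrimingCall]
) -> list[PrimingCall]:
    """Attach organ classes (root_only / leaf_only / both) to the calls.

    A gene is "both" when it has a call in each organ; its two calls may
    disagree in priming direction, which sets the cross-organ discordance
    flag on both.
    """
    root_by_gene = {c.gene_id: c for c in root_calls}
    leaf_by_gene = {c.gene_id: c for c in leaf_calls}
    out: list[PrimingCall] = []
    for call in root_calls + leaf_calls:
        in_root = call.gene_id in root_by_gene
        in_leaf = call.gene_id in leaf_by_gene
        if in_root and in_leaf:
            organ_class = "both"
            discordant = (
                root_by_gene[call.gene_id].priming_direction
                != leaf_by_gene[call.gene_id].priming_direction
            )
        else:
            organ_class = "root_only" if in_root else "leaf_only"
            discordant = False
        out.append(replace(call, organ_class=organ_class, cross_organ_discordant=discordant))
    return out


def overlap_with_tolerant_degs(
    calls: list[PrimingCall],
) -> dict[str, dict[str, int]]:
    """Per organ class, how many candidates are also drought-DE in the
    tolerant genotype (counted per organ for the "both" class)."""
    summary: dict[str, dict[str, int]] = {}
    for organ_class in ("root_only", "leaf_only", "both"):
        class_calls = [c for c in calls if c.organ_class == organ_class]
        genes = {c.gene_id for c in class_calls}
        per_organ: dict[str, int] = {}
        for organ in ("root", "leaf"):
            per_organ[organ] = len(
                {
                    c.gene_id
                    for c in class_calls
                    if c.organ == organ and c.tolerant_drought_overlap
                }
            )
        summary[organ_class] = {
            "n_candidates": len(genes),
            "overlap_root": per_organ["root"],
            "overlap_leaf": per_organ["leaf"],
        }
    return summary


def calls_to_frame(calls: list[PrimingCall]) -> pd.DataFrame:
    """Flatten calls into the output table schema."""
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "organ": c.organ,
                "priming_direction": c.priming_direction,
                "organ_class": c.organ_class,
                "initial_FC": c.initial_fc,
                "initial_q": c.initial_q,
                "sensitive_drought_FC": c.sensitive_drought_fc,
                "sensitive_drought_q": c.sensitive_drought_q,
                "tolerant_overlap": c.tolerant_drought_overlap,
                "cross_organ_discordant": c.cross_organ_discordant,
            }
            for c in calls
        ]
    )
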