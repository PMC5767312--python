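"""Synthetic expression data with planted ground truth.

The generator emulates the study design the pipeline targets: 2 genotypes
(drought-tolerant, drought-sensitive) × 2 organs (leaf, root) × 2
conditions (control, drought) with replicated single-channel arrays,
many-to-one probe→gene mapping, per-array scaling offsets, planted drought
DEGs, planted "primed" genes (an initial between-genotype difference that
the sensitive genotype reproduces only under drought), GO terms enriched
in the planted sets, and qPCR plates concordant with the array fold
changes.

Construction is on the log2 scale. Every gene gets a baseline level and a
per-gene organ offset (organs are distinct tissues, so most genes differ
between them — this is what makes organ the dominant clustering factor).
Planted effects are added on top of the baseline as cell-mean shifts:

* drought DEGs: a drought response of magnitude ≥ ``condition_effect`` in
  the affected genotype(s) and organ(s);
* primed genes: the tolerant genotype sits ``≥ delta_init`` above (or
  below) the sensitive genotype in *both* conditions, and the sensitive
  genotype moves by ``≥ delta_drought`` toward the tolerant level under
  drought;
* initial-difference-only genes: a constitutive between-genotype offset of
  magnitude ≥ ``genotype_effect`` with no drought response (decoys for the
  priming rule).

Planted magnitudes are drawn uniformly on [delta, delta + effect_spread]:
real drought responses span a wide fold-change range, and the planted
deltas are lower bounds by construction. Probe values are the gene's cell
mean plus a constant per-probe offset plus i.i.d. Gaussian noise; a
per-array additive log2 offset (multiplicative on the linear scale)
exercises the percentile-shift normalization. Ground-truth labels are
re-derived from the stored noiseless cell means with the analysis
thresholds, so labels and generating means agree by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from droughtprime.normalize import CONDITIONS, GENOTYPES, ORGANS

GENOTYPE_CLASSES = ("tolerant_only", "sensitive_only", "shared")
ORGAN_CLASSES = ("root_only", "leaf_only", "both")
DIRECTIONS = ("up", "down")

LOG2_TAU_INIT = 1.0  # log2(2)
LOG2_TAU_DROUGHT = math.log2(3.0)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the generator (all effects in log2 units)."""

    n_genes: int = 1200
    probes_per_gene_range: tuple[int, int] = (1, 3)
    n_replicates: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    # effect hierarchy: organ > condition > genotype
    organ_effect: float = 2.5  # sd of the per-gene organ offset (all genes)
    condition_effect: float = 2.0  # min |drought response| of planted DEGs (≥ log2 3)
    genotype_effect: float = 1.5  # min |initial difference| of decoy genes (≥ log2 2)
    n_deg_per_class: int = 10  # per (genotype-class × organ-class × direction) cell
    n_primed_high: int = 8  # per organ class
    n_primed_low: int = 8  # per organ class
    n_init_only: int = 20  # per organ class
    delta_init: float = 1.5  # min planted initial difference of primed genes
    delta_drought: float = 2.0  # min planted sensitive drought response of primed genes
    # fraction of primed genes that also respond (usually more weakly) in the
    # tolerant genotype, so candidate/tolerant-DEG overlap is represented
    primed_tolerant_response_fraction: float = 0.25
    effect_spread: float = 2.5  # planted magnitudes ~ U[delta, delta + spread]
    noise_sd: float = 0.5
    probe_offset_sd: float = 0.3
    array_offset_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_replicates": self.n_replicates,
            "n_deg_per_class": self.n_deg_per_class,
            "n_primed_high": self.n_primed_high,
            "n_primed_low": self.n_primed_low,
            "n_init_only": self.n_init_only,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be ≥ 0, got {value}")
        if self.delta_init <= 0 or self.delta_drought <= 0:
            raise ConfigurationError("delta_init and delta_drought must be > 0")
        if self.noise_sd < 0 or self.array_offset_sd < 0 or self.probe_offset_sd < 0:
            raise ConfigurationError("noise/offset standard deviations must be ≥ 0")
        lo, hi = self.probes_per_gene_range
        if not 1 <= lo <= hi:
            raise ConfigurationError(f"bad probes_per_gene_range {self.probes_per_gene_range}")
        if self.n_planted > self.n_genes:
            raise ConfigurationError(
                f"planted gene sets ({self.n_planted}) exceed n_genes ({self.n_genes})"
            )

    @property
    def n_planted(self) -> int:
        n_deg = self.n_deg_per_class * len(GENOTYPE_CLASSES) * len(ORGAN_CLASSES) * len(DIRECTIONS)
        n_primed = (self.n_primed_high + self.n_primed_low) * len(ORGAN_CLASSES)
        return n_deg + n_primed + self.n_init_only * len(ORGAN_CLASSES)


def _active_organs(organ_class: str) -> tuple[str, ...]:
    return {"root_only": ("root",), "leaf_only": ("leaf",), "both": ORGANS}[organ_class]


@dataclass
class GroundTruth:
    """Stored generating means plus derived per-gene labels.

    ``cell_means[g, o, t, c]`` is the noiseless log2 level of gene g in
    organ ORGANS[o], genotype GENOTYPES[t], condition CONDITIONS[c].
    Labels (drought-DEG classes, priming labels) are derived from these
    means with the analysis thresholds (FC ≥ 3 drought, FC ≥ 2 initial),
    so re-deriving them from the stored means reproduces them exactly.
    """

    gene_ids: list[str]
    cell_means: np.ndarray  # (n_genes, 2 organs, 2 genotypes, 2 conditions)
    planted: pd.DataFrame  # gene_id, role, organ_class, direction
    enriched_terms: dict[str, bool] = field(default_factory=dict)

    def _gene_pos(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def deg_table(self) -> pd.DataFrame:
        """Per (gene, organ): true drought-DE status per genotype and the
        genotype-exclusivity class, thresholded at |Δ| ≥ log2(3)."""
        rows = []
        for gi, gene in enumerate(self.gene_ids):
            for oi, organ in enumerate(ORGANS):
                flags = {}
                dirs = {}
                for ti, genotype in enumerate(GENOTYPES):
                    delta = (
                        self.cell_means[gi, oi, ti, CONDITIONS.index("drought")]
                        - self.cell_means[gi, oi, ti, CONDITIONS.index("control")]
                    )
                    flags[genotype] = abs(delta) >= LOG2_TAU_DROUGHT
                    dirs[genotype] = "up" if delta > 0 else ("down" if delta < 0 else "none")
                if flags["tolerant"] and flags["sensitive"]:
                    deg_class = "shared"
                elif flags["tolerant"]:
                    deg_class = "tolerant_only"
                elif flags["sensitive"]:
                    deg_class = "sensitive_only"
                else:
                    deg_class = "none"
                rows.append(
                    {
                        "gene_id": gene,
                        "organ": organ,
                        "deg_class": deg_class,
                        "tolerant_direction": dirs["tolerant"] if flags["tolerant"] else "none",
                        "sensitive_direction": dirs["sensitive"] if flags["sensitive"] else "none",
                    }
                )
        return pd.DataFrame(rows)

    def priming_table(self) -> pd.DataFrame:
        """Per (gene, organ): primed_high / primed_low / none from the
        stored means (initial |Δ| ≥ log2 2, sensitive drought |Δ| ≥ log2 3,
        direction-consistent)."""
        oc, od = CONDITIONS.index("control"), CONDITIONS.index("drought")
        tt, ts = GENOTYPES.index("tolerant"), GENOTYPES.index("sensitive")
        rows = []
        for gi, gene in enumerate(self.gene_ids):
            for oi, organ in enumerate(ORGANS):
                init = self.cell_means[gi, oi, tt, oc] - self.cell_means[gi, oi, ts, oc]
                sdelta = self.cell_means[gi, oi, ts, od] - self.cell_means[gi, oi, ts, oc]
                if init >= LOG2_TAU_INIT and sdelta >= LOG2_TAU_DROUGHT:
                    label = "primed_high"
                elif init <= -LOG2_TAU_INIT and sdelta <= -LOG2_TAU_DROUGHT:
                    label = "primed_low"
                else:
                    label = "none"
                rows.append({"gene_id": gene, "organ": organ, "primed_label": label})
        return pd.DataFrame(rows)

    def primed_genes(self, organ: str | None = None) -> set[str]:
        table = self.priming_table()
        mask = table["primed_label"] != "none"
        if organ is not None:
            mask &= table["organ"] == organ
        return set(table.loc[mask, "gene_id"])

    def deg_genes(self, organ: str, genotype: str | None = None) -> set[str]:
        table = self.deg_table()
        sub = table[table["organ"] == organ]
        if genotype is None:
            return set(sub.loc[sub["deg_class"] != "none", "gene_id"])
        col = f"{genotype}_direction"
        return set(sub.loc[sub[col] != "none", "gene_id"])

    def labels_frame(self) -> pd.DataFrame:
        """Long truth-label table (gene, organ, deg_class, directions,
        primed_label) for the truth TSV."""
        return self.deg_table().merge(self.priming_table(), on=["gene_id", "organ"])


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one complete experiment.

    Returns (raw linear-scale matrix probes × samples, sample sheet,
    probe→gene map, ground truth). Identical config (incl. seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"G{i + 1:06d}" for i in range(n)]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n)
    organ_offset = rng.normal(0.0, config.organ_effect, n) if config.organ_effect > 0 else np.zeros(n)

    # cell_means[g, organ, genotype, condition]
    means = np.zeros((n, 2, 2, 2))
    means += baseline[:, None, None, None]
    means[:, ORGANS.index("root"), :, :] += organ_offset[:, None, None]

    planted_rows: list[dict] = []
    pool = list(rng.permutation(n))

    def take(k: int) -> list[int]:
        picked = pool[:k]
        del pool[:k]
        return picked

    def draw_mag(low: float, size: int) -> np.ndarray:
        return rng.uniform(low, low + config.effect_spread, size)

    od = CONDITIONS.index("drought")
    oc = CONDITIONS.index("control")

    # planted drought DEGs
    for organ_class in ORGAN_CLASSES:
        for genotype_class in GENOTYPE_CLASSES:
            affected = (
                ("tolerant",)
                if genotype_class == "tolerant_only"
                else ("sensitive",)
                if genotype_class == "sensitive_only"
                else GENOTYPES
            )
            for direction in DIRECTIONS:
                sign = 1.0 if direction == "up" else -1.0
                for gi in take(config.n_deg_per_class):
                    for organ in _active_organs(organ_class):
                        oi = ORGANS.index(organ)
                        mag = draw_mag(config.condition_effect, 1)[0]
                        for genotype in affected:
                            means[gi, oi, GENOTYPES.index(genotype), od] += sign * mag
                    planted_rows.append(
                        {
                            "gene_id": gene_ids[gi],
                            "role": f"deg_{genotype_class}",
                            "organ_class": organ_class,
                            "direction": direction,
                        }
                    )

    # primed genes: tolerant holds the shifted level constitutively,
    # sensitive reaches it only under drought
    ts = GENOTYPES.index("sensitive")
    tt = GENOTYPES.index("tolerant")
    for organ_class in ORGAN_CLASSES:
        for label, count in (("primed_high", config.n_primed_high), ("primed_low", config.n_primed_low)):
            sign = 1.0 if label == "primed_high" else -1.0
            for gi in take(count):
                responds_in_tolerant = rng.random() < config.primed_tolerant_response_fraction
                for organ in _active_organs(organ_class):
                    oi = ORGANS.index(organ)
                    init_mag = draw_mag(config.delta_init, 1)[0]
                    drought_mag = draw_mag(config.delta_drought, 1)[0]
                    means[gi, oi, tt, :] += sign * init_mag  # both conditions
                    means[gi, oi, ts, od] += sign * drought_mag
                    if responds_in_tolerant:
                        # weaker than the sensitive response on average but
                        # still past the drought fold-change threshold
                        tol_mag = rng.uniform(
                            config.delta_drought, config.delta_drought + config.effect_spread / 2
                        )
                        means[gi, oi, tt, od] += sign * tol_mag
                planted_rows.append(
                    {
                        "gene_id": gene_ids[gi],
                        "role": label,
                        "organ_class": organ_class,
                        "direction": "up" if label == "primed_high" else "down",
                    }
                )

    # constitutive initial-difference decoys (no drought response)
    for organ_class in ORGAN_CLASSES:
        for gi in take(config.n_init_only):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            for organ in _active_organs(organ_class):
                oi = ORGANS.index(organ)
                mag = draw_mag(config.genotype_effect, 1)[0]
                means[gi, oi, tt, :] += sign * mag
            planted_rows.append(
                {
                    "gene_id": gene_ids[gi],
                    "role": "init_only",
                    "organ_class": organ_class,
                    "direction": "up" if sign > 0 else "down",
                }
            )

    truth = GroundTruth(
        gene_ids=gene_ids,
        cell_means=means,
        planted=pd.DataFrame(planted_rows, columns=["gene_id", "role", "organ_class", "direction"]),
    )

    # probes
    lo, hi = config.probes_per_gene_range
    n_probes_per_gene = rng.integers(lo, hi + 1, n)
    probe_ids: list[str] = []
    probe_gene_idx: list[int] = []
    for gi in range(n):
        for j in range(n_probes_per_gene[gi]):
            probe_ids.append(f"{gene_ids[gi]}_p{j + 1}")
            probe_gene_idx.append(gi)
    probe_gene_idx = np.asarray(probe_gene_idx)
    n_probes = len(probe_ids)
    probe_offsets = (
        rng.normal(0.0, config.probe_offset_sd, n_probes)
        if config.probe_offset_sd > 0
        else np.zeros(n_probes)
    )

    # samples: organ-major ordering
    sample_rows = []
    for organ in ORGANS:
        for genotype in GENOTYPES:
            for condition in CONDITIONS:
                for rep in range(1, config.n_replicates + 1):
                    sample_rows.append(
                        {
                            "sample_id": f"{genotype}_{organ}_{condition}_r{rep}",
                            "genotype": genotype,
                            "organ": organ,
                            "condition": condition,
                            "replicate": rep,
                        }
                    )
    samples = pd.DataFrame(sample_rows)
    n_samples = len(samples)
    array_offsets = (
        rng.normal(0.0, config.array_offset_sd, n_samples)
        if config.array_offset_sd > 0
        else np.zeros(n_samples)
    )

    log2m = np.empty((n_probes, n_samples))
    for si, row in samples.iterrows():
        oi = ORGANS.index(row["organ"])
        ti = GENOTYPES.index(row["genotype"])
        ci = CONDITIONS.index(row["condition"])
        cell = means[probe_gene_idx, oi, ti, ci]
        noise = rng.normal(0.0, config.noise_sd, n_probes) if config.noise_sd > 0 else 0.0
        log2m[:, si] = cell + probe_offsets + noise + array_offsets[si]

    raw = pd.DataFrame(
        2.0**log2m, index=pd.Index(probe_ids, name="probe_id"), columns=samples["sample_id"]
    )
    probe_map = pd.DataFrame(
        {"probe_id": probe_ids, "gene_id": [gene_ids[g] for g in probe_gene_idx]}
    )
    return raw, samples, probe_map, truth


# ---------------------------------------------------------------------------
# GO annotations


def simulate_go_annotations(
    truth: GroundTruth,
    n_terms: int = 30,
    enrichment_factor: float = 5.0,
    seed: int = 0,
    base_prob: float = 0.05,
    n_enriched_terms: int = 6,
) -> tuple[dict[str, set[str]], nx.DiGraph, pd.DataFrame]:
    """Random gene→term annotations with designated planted-enriched terms.

    Builds a small is_a DAG (leaf terms → intermediate parents → one
    namespace root). Background genes pick up each leaf term with
    ``base_prob``; for a designated term, genes of its target planted set
    (cycling over root DEGs, leaf DEGs, primed genes) are annotated with
    probability ``base_prob × enrichment_factor``. With
    enrichment_factor = 1 no term is enriched.

    Returns (annotations, dag, term table with planted-enriched flags);
    also records the flags on ``truth.enriched_terms``.
    """
    if n_terms < 1:
        raise ConfigurationError("n_terms must be ≥ 1")
    if enrichment_factor < 1:
        raise ConfigurationError("enrichment_factor must be ≥ 1")
    rng = np.random.default_rng(seed)

    root = "GO:0008150"
    n_parents = max(2, n_terms // 10)
    parents = [f"GO:{1000000 + i:07d}" for i in range(n_parents)]
    leaves = [f"GO:{2000000 + i:07d}" for i in range(n_terms)]
    dag = nx.DiGraph()
    dag.add_node(root, name="biological_process")
    for i, parent in enumerate(parents):
        dag.add_node(parent, name=f"synthetic process group {i + 1}")
        dag.add_edge(parent, root, relation="is_a")
    for i, leaf in enumerate(leaves):
        dag.add_node(leaf, name=f"synthetic process {i + 1}")
        dag.add_edge(leaf, parents[i % n_parents], relation="is_a")

    target_sets = [
        ("root_degs", truth.deg_genes("root")),
        ("leaf_degs", truth.deg_genes("leaf")),
        ("primed", truth.primed_genes()),
    ]
    enriched: dict[str, bool] = {}
    term_target: dict[str, str] = {}
    designated = leaves[: min(n_enriched_terms, n_terms)]
    for i, term in enumerate(designated):
        name, genes = target_sets[i % len(target_sets)]
        term_target[term] = name
        enriched[term] = enrichment_factor > 1 and len(genes) > 0
    for term in leaves:
        enriched.setdefault(term, False)
        term_target.setdefault(term, "")

    gene_sets = {name: genes for name, genes in target_sets}
    annotations: dict[str, set[str]] = {g: set() for g in truth.gene_ids}
    for term in leaves:
        target = gene_sets.get(term_target[term], set()) if enriched[term] else set()
        p_in = min(0.95, base_prob * enrichment_factor)
        for gene in truth.gene_ids:
            p = p_in if gene in target else base_prob
            if rng.random() < p:
                annotations[gene].add(term)

    truth.enriched_terms = enriched
    term_table = pd.DataFrame(
        {
            "term": leaves,
            "description": [dag.nodes[t]["name"] for t in leaves],
            "planted_enriched": [enriched[t] for t in leaves],
            "target_set": [term_target[t] for t in leaves],
        }
    )
    return annotations, dag, term_table


# ---------------------------------------------------------------------------
# qPCR


@dataclass
class QpcrPlate:
    """Simulated plate: well-level Ct values plus the generating parameters."""

    wells: pd.DataFrame  # well, amplicon, sample, condition, replicate, Ct
    efficiencies: dict[str, float]  # amplicon → true E
    reference_gene: str
    curves: dict[str, np.ndarray] = field(default_factory=dict)  # well → fluorescence


def simulate_amplification_curve(
    efficiency: float,
    ct: float,
    n_cycles: int = 40,
    threshold: float = 1.0,
    plateau: float = 100.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Raw fluorescence F(c) = threshold · E^(c − Ct), capped at the
    plateau, cycles 1..n_cycles."""
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    f = threshold * efficiency ** (cycles - ct)
    f = np.minimum(f, plateau * threshold)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        f = f * (1.0 + rng.normal(0.0, noise_sd, f.shape))
    return f


def simulate_qpcr(
    truth: GroundTruth,
    genes: list[str],
    organ: str,
    genotype: str,
    n_replicates: int = 3,
    reference_gene: str = "REF_ARF1",
    reference_level: float = 8.0,
    ct_intercept: float = 35.0,
    ct_noise_sd: float = 0.15,
    efficiency_range: tuple[float, float] = (1.8, 2.0),
    seed: int = 0,
    with_curves: bool = False,
) -> QpcrPlate:
    """Simulate a drought-vs-control qPCR plate for selected genes.

    Ct is generated as ``ct_intercept − log_E(2^level)`` plus Gaussian
    noise, per-amplicon E drawn uniformly in ``efficiency_range``; the
    reference amplicon is condition-invariant at ``reference_level`` log2
    units. Levels come from the stored noiseless truth means, so the
    planted linear fold change reappears downstream as the Pfaffl ratio.
    """
    if reference_gene in genes:
        raise ConfigurationError(f"reference gene {reference_gene!r} is in the varying gene set")
    pos = {g: i for i, g in enumerate(truth.gene_ids)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ConfigurationError(f"gene(s) not in ground truth: {missing}")
    if organ not in ORGANS or genotype not in GENOTYPES:
        raise ConfigurationError(f"unknown organ/genotype {organ!r}/{genotype!r}")

    rng = np.random.default_rng(seed)
    oi, ti = ORGANS.index(organ), GENOTYPES.index(genotype)
    amplicons = list(genes) + [reference_gene]
    efficiencies = {
        a: float(rng.uniform(*efficiency_range)) for a in amplicons
    }

    rows = []
    curves: dict[str, np.ndarray] = {}
    well = 0
    for amplicon in amplicons:
        e = efficiencies[amplicon]
        for condition in CONDITIONS:
            if amplicon == reference_gene:
                level = reference_level
            else:
                level = truth.cell_means[pos[amplicon], oi, ti, CONDITIONS.index(condition)]
            ct_true = ct_intercept - level * math.log(2.0) / math.log(e)
            for rep in range(1, n_replicates + 1):
                well += 1
                ct = ct_true + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                well_id = f"W{well:03d}"
                rows.append(
                    {
                        "well": well_id,
                        "amplicon": amplicon,
                        "sample": f"{genotype}_{organ}_{condition}_r{rep}",
                        "condition": condition,
                        "replicate": rep,
                        "Ct": ct,
                    }
                )
                if with_curves:
                    curves[well_id] = simulate_amplification_curve(e, ct)
    return QpcrPlate(
        wells=pd.DataFrame(rows),
        efficiencies=efficiencies,
        reference_gene=reference_gene,
        curves=curves,
    )


def noiseless(config: SimulationConfig) -> SimulationConfig:
    """A copy of the config with every noise source switched off."""
    return replace(
        config, noise_sd=0.0, probe_offset_sd=0.0, array_offset_sd=0.0, effect_spread=0.0
    )
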