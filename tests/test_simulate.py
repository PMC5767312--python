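"""The ground-truth generator: noiseless exactness, determinism, label
consistency, and the planted effect hierarchy."""

import numpy as np
import pandas as pd
import pytest

from droughtprime.normalize import CONDITIONS, GENOTYPES, ORGANS
from droughtprime.qpcr import pfaffl_ratio
from droughtprime.simulate import (
    ConfigurationError,
    SimulationConfig,
    noiseless,
    simulate_dataset,
    simulate_go_annotations,
    simulate_qpcr,
)


def single_primed_config(**overrides):
    base = dict(
        n_genes=5, probes_per_gene_range=(1, 1), n_deg_per_class=0,
        n_primed_high=0, n_primed_low=0, n_init_only=0, organ_effect=0.0,
        noise_sd=0.0, probe_offset_sd=0.0, array_offset_sd=0.0,
        effect_spread=0.0, baseline_sd=0.0, seed=0,
        primed_tolerant_response_fraction=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestNoiselessConstruction:
    def test_primed_gene_cell_means_exact(self):
        config = single_primed_config(
            n_primed_high=1, delta_init=1.0, delta_drought=2.0
        )
        raw, samples, _, truth = simulate_dataset(config)
        primed = truth.planted[truth.planted["role"] == "primed_high"]
        gi = truth.gene_ids.index(primed["gene_id"].iloc[0])
        oi = ORGANS.index("root")  # first organ class cell is root_only
        tt, ts = GENOTYPES.index("tolerant"), GENOTYPES.index("sensitive")
        oc, od = CONDITIONS.index("control"), CONDITIONS.index("drought")
        m = truth.cell_means
        assert m[gi, oi, tt, oc] - m[gi, oi, ts, oc] == pytest.approx(1.0)
        assert m[gi, oi, ts, od] - m[gi, oi, ts, oc] == pytest.approx(2.0)
        assert m[gi, oi, tt, od] == pytest.approx(m[gi, oi, tt, oc])
        # observed log2 values equal cell means exactly (no noise sources)
        log2 = np.log2(raw.to_numpy())
        sheet = samples.set_index("sample_id")
        probe = f"{truth.gene_ids[gi]}_p1"
        for sid in raw.columns:
            o = ORGANS.index(sheet.loc[sid, "organ"])
            t = GENOTYPES.index(sheet.loc[sid, "genotype"])
            c = CONDITIONS.index(sheet.loc[sid, "condition"])
            assert log2[raw.index.get_loc(probe), raw.columns.get_loc(sid)] == pytest.approx(
                m[gi, o, t, c]
            )

    def test_observed_fold_change_equals_planted(self, noiseless_dataset):
        _, raw, samples, probe_map, truth = noiseless_dataset
        sheet = samples.set_index("sample_id")
        log2 = np.log2(raw)
        deg = truth.deg_table()
        planted_deg = deg[(deg["deg_class"] == "sensitive_only") & (deg["organ"] == "root")]
        assert len(planted_deg)
        gene = planted_deg["gene_id"].iloc[0]
        probes = probe_map.loc[probe_map["gene_id"] == gene, "probe_id"]
        cols_d = sheet[(sheet["organ"] == "root") & (sheet["genotype"] == "sensitive")
                       & (sheet["condition"] == "drought")].index
        cols_c = sheet[(sheet["organ"] == "root") & (sheet["genotype"] == "sensitive")
                       & (sheet["condition"] == "control")].index
        observed = log2.loc[probes, cols_d].mean(axis=1) - log2.loc[probes, cols_c].mean(axis=1)
        gi = truth.gene_ids.index(gene)
        oi, ts = ORGANS.index("root"), GENOTYPES.index("sensitive")
        planted = truth.cell_means[gi, oi, ts, 1] - truth.cell_means[gi, oi, ts, 0]
        np.testing.assert_allclose(observed, planted, atol=1e-10)


class TestDeterminismAndValidation:
    @staticmethod
    def small(seed):
        return SimulationConfig(
            seed=seed, n_genes=100, n_deg_per_class=1, n_primed_high=1,
            n_primed_low=1, n_init_only=2,
        )

    def test_same_seed_bit_identical(self):
        raw1, s1, pm1, t1 = simulate_dataset(self.small(5))
        raw2, s2, pm2, t2 = simulate_dataset(self.small(5))
        pd.testing.assert_frame_equal(raw1, raw2)
        pd.testing.assert_frame_equal(pm1, pm2)
        np.testing.assert_array_equal(t1.cell_means, t2.cell_means)

    def test_different_seed_differs(self):
        a, *_ = simulate_dataset(self.small(1))
        b, *_ = simulate_dataset(self.small(2))
        assert not a.equals(b)

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ConfigurationError, match="exceed"):
            SimulationConfig(n_genes=10, n_deg_per_class=5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_replicates=-1)
        with pytest.raises(ConfigurationError):
            SimulationConfig(delta_init=0.0)


class TestLabelConsistency:
    def test_planted_roles_match_derived_labels(self, default_dataset):
        _, _, _, _, truth = default_dataset
        priming = truth.priming_table()
        primed_lookup = {
            (r.gene_id, r.organ): r.primed_label for r in priming.itertuples()
        }
        for row in truth.planted.itertuples():
            if row.role not in ("primed_high", "primed_low"):
                continue
            organs = {"root_only": ["root"], "leaf_only": ["leaf"], "both": ["root", "leaf"]}[
                row.organ_class
            ]
            for organ in organs:
                assert primed_lookup[(row.gene_id, organ)] == row.role
        # no unplanned primed labels
        planted_primed = set(
            truth.planted.loc[
                truth.planted["role"].isin(["primed_high", "primed_low"]), "gene_id"
            ]
        )
        derived_primed = set(priming.loc[priming["primed_label"] != "none", "gene_id"])
        assert derived_primed == planted_primed

    def test_relabelling_from_stored_means_is_stable(self, default_dataset):
        _, _, _, _, truth = default_dataset
        pd.testing.assert_frame_equal(truth.deg_table(), truth.deg_table())


def test_distance_ordering_follows_effect_hierarchy(default_dataset):
    """Mean between-organ distance > between-condition > between-genotype."""
    _, raw, samples, _, _ = default_dataset
    from droughtprime.clustering import distance_matrix
    from droughtprime.normalize import normalize_matrix

    normalized, _ = normalize_matrix(raw)
    d = distance_matrix(normalized)
    sheet = samples.set_index("sample_id")

    def mean_between(factor):
        vals = []
        for i, si in enumerate(d.index):
            for sj in d.index[i + 1 :]:
                others = [f for f in ("organ", "condition", "genotype") if f != factor]
                if sheet.loc[si, factor] != sheet.loc[sj, factor] and all(
                    sheet.loc[si, f] == sheet.loc[sj, f] for f in others
                ):
                    vals.append(d.loc[si, sj])
        return np.mean(vals)

    organ, condition, genotype = (
        mean_between("organ"), mean_between("condition"), mean_between("genotype")
    )
    assert organ > condition > genotype


class TestGoAnnotations:
    def test_null_factor_plants_nothing(self, default_dataset):
        _, _, _, _, truth = default_dataset
        _, _, terms = simulate_go_annotations(truth, enrichment_factor=1.0, seed=0)
        assert not terms["planted_enriched"].any()

    def test_seed_reproducible(self, default_dataset):
        _, _, _, _, truth = default_dataset
        ann1, _, t1 = simulate_go_annotations(truth, seed=9)
        ann2, _, t2 = simulate_go_annotations(truth, seed=9)
        assert ann1 == ann2
        pd.testing.assert_frame_equal(t1, t2)

    def test_dag_is_acyclic_with_root(self, default_dataset):
        import networkx as nx

        _, _, _, _, truth = default_dataset
        _, dag, _ = simulate_go_annotations(truth, seed=0)
        assert nx.is_directed_acyclic_graph(dag)
        sinks = [n for n in dag if dag.out_degree(n) == 0]
        assert sinks == ["GO:0008150"]


class TestQpcrPlate:
    def test_reference_in_varying_set_rejected(self, noiseless_dataset):
        _, _, _, _, truth = noiseless_dataset
        with pytest.raises(ConfigurationError, match="reference"):
            simulate_qpcr(truth, ["REF_ARF1"], "root", "sensitive")

    def test_noiseless_planted_fc_reappears_as_pfaffl_ratio(self, noiseless_dataset):
        _, _, _, _, truth = noiseless_dataset
        deg = truth.deg_table()
        gene = deg[(deg["deg_class"] == "sensitive_only") & (deg["organ"] == "root")][
            "gene_id"
        ].iloc[0]
        plate = simulate_qpcr(
            truth, [gene], "root", "sensitive", ct_noise_sd=0.0,
            efficiency_range=(2.0, 2.0), seed=0,
        )
        wells = plate.wells
        def mean_ct(amplicon, condition):
            sel = (wells["amplicon"] == amplicon) & (wells["condition"] == condition)
            return wells.loc[sel, "Ct"].mean()

        dct_t = mean_ct(gene, "control") - mean_ct(gene, "drought")
        dct_r = mean_ct("REF_ARF1", "control") - mean_ct("REF_ARF1", "drought")
        ratio = pfaffl_ratio(2.0, dct_t, 2.0, dct_r)
        gi = truth.gene_ids.index(gene)
        planted = 2.0 ** (
            truth.cell_means[gi, ORGANS.index("root"), GENOTYPES.index("sensitive"), 1]
            - truth.cell_means[gi, ORGANS.index("root"), GENOTYPES.index("sensitive"), 0]
        )
        assert ratio == pytest.approx(planted, rel=1e-9)

    def test_reference_vs_itself_unity(self, noiseless_dataset):
        _, _, _, _, truth = noiseless_dataset
        plate = simulate_qpcr(truth, [], "leaf", "tolerant", ct_noise_sd=0.0, seed=1)
        wells = plate.wells
        ref = wells[wells["amplicon"] == "REF_ARF1"]
        dct = (
            ref.loc[ref["condition"] == "control", "Ct"].mean()
            - ref.loc[ref["condition"] == "drought", "Ct"].mean()
        )
        e = plate.efficiencies["REF_ARF1"]
        assert pfaffl_ratio(e, dct, e, dct) == pytest.approx(1.0)
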