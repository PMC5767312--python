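"""Two-factor cell-means fits, pooled-variance contrasts, BH adjustment and
probe→gene collapse, each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from droughtprime.diffexpr import (
    DROUGHT_VS_CONTROL,
    TOLERANT_VS_SENSITIVE_CONTROL,
    ContrastSpec,
    DesignError,
    MappingError,
    bh_adjust,
    call_probe_degs,
    collapse_probes_to_genes,
    contrast_test,
    fit_cell_means,
    run_contrast,
)

CELLS = [("tolerant", "control"), ("tolerant", "drought"),
         ("sensitive", "control"), ("sensitive", "drought")]


def build_design(values_by_cell, organ="root", n_rep=3):
    """Matrix + sheet for one organ; values_by_cell: cell -> per-probe list of reps."""
    columns, rows = [], {}
    sheet_rows = []
    for genotype, condition in CELLS:
        for rep in range(1, n_rep + 1):
            sid = f"{genotype}_{organ}_{condition}_r{rep}"
            columns.append(sid)
            sheet_rows.append(
                {"sample_id": sid, "genotype": genotype, "organ": organ,
                 "condition": condition, "replicate": rep}
            )
    n_probes = len(next(iter(values_by_cell.values()))[0]) if values_by_cell else 0
    data = np.zeros((len(values_by_cell[CELLS[0]]), len(columns)))
    for j, (genotype, condition) in enumerate(CELLS):
        reps = np.asarray(values_by_cell[(genotype, condition)], float)  # (probes, n_rep)
        data[:, j * n_rep : (j + 1) * n_rep] = reps
    matrix = pd.DataFrame(
        data, index=[f"p{i}" for i in range(data.shape[0])],
        columns=[f"{g}_{organ}_{c}_r{r}" for (g, c) in CELLS for r in range(1, n_rep + 1)],
    )
    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    return matrix, sheet


class TestFitCellMeans:
    def test_noiseless_cells_exact_and_zero_mse(self):
        vals = {
            ("tolerant", "control"): [[5.0, 5.0, 5.0]],
            ("tolerant", "drought"): [[5.0, 5.0, 5.0]],
            ("sensitive", "control"): [[5.0, 5.0, 5.0]],
            ("sensitive", "drought"): [[7.0, 7.0, 7.0]],
        }
        matrix, sheet = build_design(vals)
        fit = fit_cell_means(matrix, sheet, "root")
        assert fit.df == 8
        np.testing.assert_allclose(
            [fit.means[0, fit.cell_index(g, c)] for g, c in CELLS], [5, 5, 5, 7]
        )
        assert fit.mse[0] == 0.0

    def test_agrees_with_least_squares_oracle(self):
        rng = np.random.default_rng(11)
        vals = {cell: rng.normal(5, 1, (6, 3)) for cell in CELLS}
        matrix, sheet = build_design(vals)
        fit = fit_cell_means(matrix, sheet, "root")
        # independent oracle: one-hot design matrix, normal equations per probe
        X = np.zeros((12, 4))
        y_cols = []
        for j, cell in enumerate(CELLS):
            X[j * 3 : (j + 1) * 3, j] = 1.0
            y_cols.append(np.asarray(vals[cell]))
        Y = np.hstack(y_cols)  # (probes, 12)
        beta, res, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
        np.testing.assert_allclose(fit.means, beta.T, atol=1e-10)
        np.testing.assert_allclose(fit.mse, res / 8.0, atol=1e-10)

    def test_single_replicate_cell_is_design_error(self):
        vals = {cell: [[1.0, 2.0, 3.0]] for cell in CELLS}
        matrix, sheet = build_design(vals)
        drop = [c for c in matrix.columns if c.startswith("tolerant_root_control")][1:]
        with pytest.raises(DesignError, match="tolerant"):
            fit_cell_means(matrix.drop(columns=drop), sheet.drop(index=drop), "root")


class TestContrastTest:
    def test_zero_delta_with_noise_gives_p_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 3)
        vals = {cell: [list(base)] for cell in CELLS}
        matrix, sheet = build_design(vals)
        # same replicate values in every cell: delta = 0 with MSE > 0
        fit = fit_cell_means(matrix, sheet, "root")
        assert fit.mse[0] > 0
        spec = ContrastSpec("root", DROUGHT_VS_CONTROL, genotype="sensitive")
        out = contrast_test(fit, spec)
        assert out["FC"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_noiseless_degenerate_rule(self):
        vals = {
            ("tolerant", "control"): [[5.0] * 3],
            ("tolerant", "drought"): [[5.0] * 3],
            ("sensitive", "control"): [[5.0] * 3],
            ("sensitive", "drought"): [[7.0] * 3],
        }
        matrix, sheet = build_design(vals)
        fit = fit_cell_means(matrix, sheet, "root")
        out = contrast_test(fit, ContrastSpec("root", DROUGHT_VS_CONTROL, genotype="sensitive"))
        assert out["FC"].iloc[0] == pytest.approx(4.0)
        assert out["p"].iloc[0] == 0.0
        flat = contrast_test(fit, ContrastSpec("root", DROUGHT_VS_CONTROL, genotype="tolerant"))
        assert flat["p"].iloc[0] == 1.0

    def test_matches_hand_pooled_t(self):
        vals = {
            ("tolerant", "control"): [[5.1, 4.8, 5.3]],
            ("tolerant", "drought"): [[5.0, 5.2, 4.9]],
            ("sensitive", "control"): [[4.0, 4.4, 4.2]],
            ("sensitive", "drought"): [[6.5, 6.1, 6.6]],
        }
        matrix, sheet = build_design(vals)
        fit = fit_cell_means(matrix, sheet, "root")
        out = contrast_test(fit, ContrastSpec("root", DROUGHT_VS_CONTROL, genotype="sensitive"))
        # brute-force pooled-variance t over the four cells
        groups = [np.array(v[0]) for v in vals.values()]
        sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
        mse = sse / 8
        delta = np.mean(vals[("sensitive", "drought")][0]) - np.mean(vals[("sensitive", "control")][0])
        t = delta / np.sqrt(mse * (1 / 3 + 1 / 3))
        p = 2 * stats.t.sf(abs(t), 8)
        assert out["delta"].iloc[0] == pytest.approx(delta)
        assert out["p"].iloc[0] == pytest.approx(p, rel=1e-12)

    def test_wrong_organ_rejected(self):
        vals = {cell: [[1.0, 2.0, 3.0]] for cell in CELLS}
        matrix, sheet = build_design(vals)
        fit = fit_cell_means(matrix, sheet, "root")
        with pytest.raises(ValueError, match="organ"):
            contrast_test(fit, ContrastSpec("leaf", TOLERANT_VS_SENSITIVE_CONTROL))


def bh_oracle(p):
    """Literal step-up: q_(i) = min_{j≥i} min(1, m p_(j) / j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_i, i in enumerate(order, start=1):
        q[i] = min(
            min(1.0, m * p[order[rank_j - 1]] / rank_j)
            for rank_j in range(rank_i, m + 1)
        )
    return q


class TestBhAdjust:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_degenerate_vectors(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_equals_step_up_oracle_on_grids(self):
        grid = [0.001, 0.01, 0.04, 0.05, 0.2, 0.5, 1.0]
        rng = np.random.default_rng(8)
        for m in range(1, 9):
            for _ in range(40):
                p = list(rng.choice(grid, size=m))
                np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_order_preserving(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCallProbeDegs:
    @pytest.mark.parametrize(
        "fc,q,expected",
        [(3.0, 0.05, True), (2.9, 0.001, False), (10.0, 0.06, False)],
    )
    def test_boundary_rules(self, fc, q, expected):
        stats_df = pd.DataFrame(
            {"delta": [np.log2(fc)], "FC": [fc], "direction": ["up"], "p": [q], "q": [q]},
            index=pd.Index(["p0"], name="probe_id"),
        )
        spec = ContrastSpec("root", DROUGHT_VS_CONTROL, genotype="sensitive")
        assert call_probe_degs(stats_df, spec)["pass"].iloc[0] == expected


class TestCollapse:
    def stats(self, rows):
        df = pd.DataFrame(rows).set_index("probe_id")
        return df

    def test_gene_with_one_passing_probe_is_up(self):
        stats_df = self.stats(
            [
                {"probe_id": "p1", "delta": 2.0, "FC": 4.0, "direction": "up", "p": 0.001, "q": 0.01, "pass": True},
                {"probe_id": "p2", "delta": 0.1, "FC": 1.1, "direction": "up", "p": 0.9, "q": 0.9, "pass": False},
            ]
        )
        pm = pd.DataFrame({"probe_id": ["p1", "p2"], "gene_id": ["g1", "g1"]})
        out = collapse_probes_to_genes(stats_df, pm)
        assert out.loc["g1", "pass_up"] and not out.loc["g1", "pass_down"]
        assert not out.loc["g1", "conflict"]
        assert out.loc["g1", "representative_probe"] == "p1"

    def test_opposite_directions_flag_conflict(self):
        stats_df = self.stats(
            [
                {"probe_id": "p1", "delta": 2.0, "FC": 4.0, "direction": "up", "p": 0.001, "q": 0.01, "pass": True},
                {"probe_id": "p2", "delta": -2.0, "FC": 4.0, "direction": "down", "p": 0.002, "q": 0.02, "pass": True},
            ]
        )
        pm = pd.DataFrame({"probe_id": ["p1", "p2"], "gene_id": ["g1", "g1"]})
        out = collapse_probes_to_genes(stats_df, pm)
        assert out.loc["g1", "conflict"]
        assert out.loc["g1", "pass_up"] and out.loc["g1", "pass_down"]

    def test_toy_set_matches_enumeration(self):
        rng = np.random.default_rng(21)
        probes = [f"p{i}" for i in range(6)]
        genes = ["g1", "g1", "g2", "g3", "g3", "g4"]
        rows = []
        for p in probes:
            passing = bool(rng.integers(2))
            direction = "up" if rng.integers(2) else "down"
            rows.append(
                {"probe_id": p, "delta": 1.0 if direction == "up" else -1.0,
                 "FC": 2.0, "direction": direction,
                 "p": float(rng.uniform()), "q": float(rng.uniform()), "pass": passing}
            )
        stats_df = self.stats(rows)
        pm = pd.DataFrame({"probe_id": probes, "gene_id": genes})
        out = collapse_probes_to_genes(stats_df, pm)
        for gene in set(genes):
            members = [r for r, g in zip(rows, genes) if g == gene]
            exp_up = any(r["pass"] and r["direction"] == "up" for r in members)
            exp_down = any(r["pass"] and r["direction"] == "down" for r in members)
            assert out.loc[gene, "pass_up"] == exp_up
            assert out.loc[gene, "pass_down"] == exp_down
            assert out.loc[gene, "conflict"] == (exp_up and exp_down)

    def test_probe_mapped_twice_rejected(self):
        stats_df = self.stats(
            [{"probe_id": "p1", "delta": 1.0, "FC": 2.0, "direction": "up",
              "p": 0.1, "q": 0.1, "pass": False}]
        )
        pm = pd.DataFrame({"probe_id": ["p1", "p1"], "gene_id": ["g1", "g2"]})
        with pytest.raises(MappingError, match="p1"):
            collapse_probes_to_genes(stats_df, pm)


def test_contrast_delta_invariant_to_normalization_offsets():
    """Column offsets removed upstream cannot change the contrast delta."""
    rng = np.random.default_rng(30)
    vals = {cell: rng.normal(5, 1, (4, 3)) for cell in CELLS}
    matrix, sheet = build_design(vals)
    spec = ContrastSpec("root", DROUGHT_VS_CONTROL, genotype="sensitive")
    from droughtprime.normalize import baseline_to_median, percentile_shift

    def normalized_delta(m):
        norm = baseline_to_median(percentile_shift(m)[0])
        return run_contrast(fit_cell_means(norm, sheet, "root"), spec)["delta"]

    offset = matrix.add(pd.Series(rng.normal(0, 3, matrix.shape[1]), index=matrix.columns), axis=1)
    np.testing.assert_allclose(normalized_delta(matrix), normalized_delta(offset), atol=1e-9)
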