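import numpy as np
import pandas as pd
import pytest
from fractions import Fraction

from tvgranger.network import (
    assemble_network,
    module_lag_matrix,
    run_phase_networks,
    validate,
)
from tvgranger.cpd import PhaseSegmentation
from tvgranger.var import SparseVARFit, VARConfig
from conftest import latent_matrix
from tvgranger.simulate import make_sparse_spec, simulate_var


def _fit(gene, coeffs, d_opt=3):
    return SparseVARFit(
        gene_id=gene,
        d_opt=d_opt,
        lambda_cv=1.0,
        lambda_escv=2.0,
        intercept=0.0,
        coefficients=coeffs,
    )


class TestAssembleNetwork:
    def test_all_zero_fits_empty_edges(self):
        net = assemble_network([_fit("A", {}), _fit("B", {})])
        assert net.edges == []
        assert set(net.graph.nodes) == {"A", "B"}

    def test_single_coefficient_single_edge(self):
        net = assemble_network([_fit("B", {("A", 2): 0.7}), _fit("A", {})])
        assert net.edges == [("A", "B", 2, 0.7)]

    def test_lag_label_is_largest_magnitude(self):
        net = assemble_network(
            [_fit("B", {("A", 1): 0.1, ("A", 3): -0.9}), _fit("A", {})]
        )
        assert net.edges == [("A", "B", 3, -0.9)]
        assert net.graph["A"]["B"]["lags"] == [1, 3]

    def test_min_lag_rule(self):
        net = assemble_network(
            [_fit("B", {("A", 1): 0.1, ("A", 3): -0.9}), _fit("A", {})],
            lag_rule="min_lag",
        )
        assert net.edges == [("A", "B", 1, 0.1)]

    def test_self_loops_excluded(self):
        net = assemble_network([_fit("A", {("A", 1): 0.9, ("B", 2): 0.3}), _fit("B", {})])
        assert net.edges == [("B", "A", 2, 0.3)]

    def test_d_opt_node_attribute(self):
        net = assemble_network([_fit("A", {}, d_opt=4), _fit("B", {}, d_opt=1)])
        assert net.graph.nodes["A"]["d_opt"] == 4
        assert net.graph.nodes["B"]["d_opt"] == 1


class TestModuleLagMatrix:
    def _modules(self):
        return pd.DataFrame(
            [["A", "p1"], ["B", "p2"], ["C", "p2"]],
            columns=["gene_id", "process"],
        )

    def test_single_edge_mean(self):
        net = assemble_network([_fit("B", {("A", 3): 0.5}), _fit("A", {}), _fit("C", {})])
        lm = module_lag_matrix(net, self._modules())
        assert lm.loc["p1", "p2"] == 3.0

    def test_empty_cells_are_missing_not_zero(self):
        net = assemble_network([_fit("B", {("A", 3): 0.5}), _fit("A", {}), _fit("C", {})])
        lm = module_lag_matrix(net, self._modules())
        assert np.isnan(lm.loc["p2", "p1"])
        assert np.isnan(lm.loc["p1", "p1"])

    def test_average_over_contributing_edges(self):
        net = assemble_network(
            [
                _fit("B", {("A", 2): 0.5}),
                _fit("C", {("A", 5): 0.4}),
                _fit("A", {}),
            ]
        )
        lm = module_lag_matrix(net, self._modules())
        assert lm.loc["p1", "p2"] == pytest.approx(3.5)

    def test_unmapped_gene_warns(self):
        net = assemble_network([_fit("B", {("Z", 1): 0.2}), _fit("Z", {})])
        with pytest.warns(UserWarning, match="missing"):
            module_lag_matrix(net, self._modules())

    def test_entries_within_lag_bounds(self):
        spec = make_sparse_spec(8, 3, 0.08, seed=0)
        data, _ = simulate_var(spec, T=90, seed=1)
        mat = latent_matrix(data)
        from tvgranger.var import fit_window

        fits = fit_window(mat, VARConfig(order=3, seed=0))
        net = assemble_network(fits)
        modules = pd.DataFrame(
            [[g, f"p{i % 3}"] for i, g in enumerate(mat.genes)],
            columns=["gene_id", "process"],
        )
        lm = module_lag_matrix(net, modules)
        vals = lm.to_numpy()
        finite = vals[np.isfinite(vals)]
        assert finite.size == 0 or (finite.min() >= 1 and finite.max() <= 3)


class TestValidate:
    @pytest.mark.parametrize(
        "tp, fp, precision, fdr",
        [(268, 76, 0.78, 0.22), (198, 78, 0.72, 0.28), (0, 5, 0.0, 1.0)],
    )
    def test_counts_reproduce_reported_rates(self, tp, fp, precision, fdr):
        predicted = [(f"t{i}", f"u{i}") for i in range(tp)] + [
            (f"x{i}", f"y{i}") for i in range(fp)
        ]
        reference = [(f"t{i}", f"u{i}") for i in range(tp)]
        if not reference:
            reference = [("zz", "ww")]
        rep = validate(predicted, reference, mode="directed")
        assert rep.tp == tp and rep.fp == fp
        assert round(rep.precision, 2) == precision
        assert round(rep.fdr, 2) == fdr

    def test_precision_plus_fdr_is_exactly_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, fp = int(rng.integers(0, 50)), int(rng.integers(1, 50))
            predicted = [(f"t{i}", f"u{i}") for i in range(tp)] + [
                (f"x{i}", f"y{i}") for i in range(fp)
            ]
            reference = [(f"t{i}", f"u{i}") for i in range(max(tp, 1))]
            rep = validate(predicted, reference, mode="directed")
            assert Fraction(rep.tp, rep.tp + rep.fp) + Fraction(
                rep.fp, rep.tp + rep.fp
            ) == 1

    def test_undirected_matching_ignores_direction(self):
        rep = validate([("A", "B")], [("B", "A")], mode="undirected")
        assert rep.tp == 1 and rep.fp == 0
        rep_dir = validate([("A", "B")], [("B", "A")], mode="directed")
        assert rep_dir.tp == 0 and rep_dir.fp == 1

    def test_duplicate_reference_rows_and_order_invariance(self):
        pred = [("A", "B"), ("C", "D")]
        ref = pd.DataFrame([("A", "B"), ("A", "B"), ("X", "Y")])
        r1 = validate(pred, ref.drop_duplicates())
        r2 = validate(list(reversed(pred)), ref)
        assert (r1.tp, r1.fp) == (r2.tp, r2.fp) == (1, 1)

    def test_empty_prediction_is_report_not_error(self):
        rep = validate([], [("A", "B")])
        assert rep.tp == 0 and rep.fp == 0 and rep.precision is None

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            validate([("A", "B")], [])


class TestRunPhaseNetworks:
    def test_three_boundaries_three_nested_networks(self):
        spec = make_sparse_spec(5, 2, 0.08, seed=4)
        data, _ = simulate_var(spec, T=96, seed=5)
        mat = latent_matrix(data)
        mat.t0, mat.dt = 0.5, 0.5
        seg = PhaseSegmentation(
            counts=np.zeros(96, dtype=int),
            boundaries_samples=[30, 50, 58],
            boundaries_hours=[15.5, 25.5, 29.5],
            intervals=[(0.5, 15.5), (0.5, 25.5), (0.5, 29.5)],
        )
        nets = run_phase_networks(mat, seg, VARConfig(order=2, seed=0, V=5))
        assert len(nets) == 3
        assert [n.window for n in nets] == seg.intervals
        for n in nets:
            assert set(n.graph.nodes) == set(mat.genes)

    def test_empty_segmentation_rejected(self):
        mat = latent_matrix(np.random.default_rng(0).normal(size=(3, 60)))
        seg = PhaseSegmentation(
            counts=np.zeros(60, dtype=int),
            boundaries_samples=[],
            boundaries_hours=[],
            intervals=[],
        )
        with pytest.raises(ValueError, match="no boundaries"):
            run_phase_networks(mat, seg)
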