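"""Free-energy network assembly, diagnostics and node estimation."""

import numpy as np
import pytest

from macrodissect.fep_network import (
    FepEdge,
    FepNetwork,
    build_network,
    combine_legs,
    cycle_closure,
    edge_hysteresis,
    read_edge_table,
    relative_dpkd,
    restraint_sensitivity,
    write_edge_table,
)
from macrodissect.synthetic_data import NetworkSpec, make_fep_network
from macrodissect.thermo import ddg_to_dpkd


class TestCombineLegs:
    def test_complex_minus_solvent(self):
        assert combine_legs(5.0, 3.0) == pytest.approx(2.0)

    def test_identical_legs_cancel(self):
        assert combine_legs(1.7, 1.7) == 0.0

    def test_sign_flip_on_reversal(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=2)
            assert combine_legs(-a, -b) == pytest.approx(-combine_legs(a, b))

    def test_missing_leg_raises(self):
        with pytest.raises(ValueError):
            combine_legs(None, 1.0)


class TestBuildNetwork:
    def test_legs_paired_by_edge_and_level(self):
        edges = [
            FepEdge("A", "B", "complex", 5.0, force_constant=1.0),
            FepEdge("A", "B", "solvent", 3.0, force_constant=1.0),
        ]
        net = build_network(edges, reference="A")
        assert net.binding_edges == [("A", "B", 2.0)]

    def test_missing_solvent_leg_names_pair(self):
        edges = [FepEdge("A", "B", "complex", 5.0)]
        with pytest.raises(ValueError, match="A->B.*solvent"):
            build_network(edges, reference="A")

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            FepEdge("A", "A", "complex", 1.0)


class TestHysteresis:
    def test_converged_edge(self):
        assert edge_hysteresis(FepEdge("A", "B", "complex", 1.2, ddG_reverse=-1.2)) == pytest.approx(0.0)

    def test_residual_gap(self):
        assert edge_hysteresis(FepEdge("A", "B", "complex", 1.2, ddG_reverse=-1.0)) == pytest.approx(0.2)

    def test_absent_reverse_reported_absent(self):
        assert edge_hysteresis(FepEdge("A", "B", "complex", 1.2)) is None

    def test_rms_hysteresis_tracks_noise(self):
        """Forward and backward each carry independent N(0, sigma) noise, so
        hysteresis ~ N(0, sigma*sqrt(2)); RMS over many edges and seeds must
        land near sigma*sqrt(2)."""
        sigma = 0.2
        values = []
        for seed in range(100):
            spec = NetworkSpec(
                node_dG={"A": 0.0, "B": -1.0, "C": 1.0},
                edges=[("A", "B"), ("B", "C"), ("C", "A")],
                noise_sigma=sigma,
                seed=seed,
            )
            values.extend(h for e in make_fep_network(spec) if (h := edge_hysteresis(e)) is not None)
        rms = float(np.sqrt(np.mean(np.square(values))))
        assert rms == pytest.approx(sigma * np.sqrt(2), rel=0.3)


class TestCycleClosure:
    def test_consistent_triangle_closes(self):
        net = FepNetwork(
            nodes=["A", "B", "C"],
            binding_edges=[("A", "B", 1.0), ("B", "C", -0.4), ("C", "A", -0.6)],
            reference="A",
        )
        result = cycle_closure(net)
        assert len(result["cycles"]) == 1
        assert result["cycles"][0]["closure_kcal_mol"] == pytest.approx(0.0, abs=1e-12)

    def test_inconsistent_triangle_reports_gap(self):
        net = FepNetwork(
            nodes=["A", "B", "C"],
            binding_edges=[("A", "B", 1.0), ("B", "C", -0.4), ("C", "A", -0.5)],
            reference="A",
        )
        result = cycle_closure(net)
        assert abs(result["cycles"][0]["closure_kcal_mol"]) == pytest.approx(0.1, abs=1e-12)

    def test_acyclic_network_empty_result(self):
        net = FepNetwork(
            nodes=["A", "B", "C"],
            binding_edges=[("A", "B", 1.0), ("B", "C", 2.0)],
            reference="A",
        )
        assert cycle_closure(net)["cycles"] == []

    def test_noise_free_additive_network_closes_exactly(self):
        spec = NetworkSpec(
            node_dG={"A": 0.0, "B": -0.8, "C": 0.5, "D": -1.2},
            edges=[("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("A", "C")],
            noise_sigma=0.0,
            seed=0,
        )
        net = build_network(make_fep_network(spec), reference="A")
        result = cycle_closure(net)
        assert result["cycles"]
        for c in result["cycles"]:
            assert c["closure_kcal_mol"] == pytest.approx(0.0, abs=1e-12)

    def test_closure_magnitude_tracks_noise_theory(self):
        """With per-edge binding noise ~ N(0, s_e) the closure of a cycle of
        length L has sigma s_e*sqrt(L); the mean |closure| over replicates
        must match the half-normal mean within a wide band."""
        sigma = 0.2
        closures = []
        for seed in range(100):
            spec = NetworkSpec(
                node_dG={"A": 0.0, "B": -1.0, "C": 0.7},
                edges=[("A", "B"), ("B", "C"), ("C", "A")],
                noise_sigma=sigma,
                seed=seed,
            )
            net = build_network(make_fep_network(spec), reference="A")
            closures.append(cycle_closure(net)["cycles"][0]["closure_kcal_mol"])
        # binding edge noise = complex - solvent legs: sigma*sqrt(2) per edge
        sigma_cycle = sigma * np.sqrt(2) * np.sqrt(3)
        expected_mean_abs = sigma_cycle * np.sqrt(2 / np.pi)
        assert np.mean(np.abs(closures)) == pytest.approx(expected_mean_abs, rel=0.35)


class TestRelativeDpkd:
    def test_two_node_closed_form(self):
        net = FepNetwork(
            nodes=["ref", "X"], binding_edges=[("ref", "X", 1.3642)], reference="ref"
        )
        result = relative_dpkd(net, temperature=298.15)
        assert result["ref"] == 0.0
        assert result["X"] == pytest.approx(-1.0000, abs=1e-4)

    def test_consistent_network_matches_path_sums(self):
        spec = NetworkSpec(
            node_dG={"A": 0.0, "B": -0.8, "C": 0.5},
            edges=[("A", "B"), ("B", "C"), ("A", "C")],
            noise_sigma=0.0,
            seed=0,
        )
        net = build_network(make_fep_network(spec), reference="A")
        result = relative_dpkd(net)
        assert result["B"] == pytest.approx(ddg_to_dpkd(-0.8), abs=1e-10)
        assert result["C"] == pytest.approx(ddg_to_dpkd(0.5), abs=1e-10)

    def test_least_squares_beats_single_path(self):
        """On a redundant noisy network the least-squares node estimate has
        lower variance than the worst single-path estimate (Gauss-Markov)."""
        truth = {"A": 0.0, "B": -1.0, "C": 0.5, "D": -0.3}
        edges = [("A", "B"), ("B", "D"), ("A", "C"), ("C", "D"), ("A", "D")]
        ls_est, path_est = [], []
        for seed in range(100):
            spec = NetworkSpec(node_dG=truth, edges=edges, noise_sigma=0.3, seed=seed)
            fep_edges = make_fep_network(spec)
            net = build_network(fep_edges, reference="A")
            ls_est.append(relative_dpkd(net)["D"])
            # single-path estimate: A->B->D
            by_pair = {(u, v): g for u, v, g in net.binding_edges}
            path_est.append(ddg_to_dpkd(by_pair[("A", "B")] + by_pair[("B", "D")]))
        assert np.var(ls_est) < np.var(path_est)

    def test_edge_reversal_invariance(self):
        spec = NetworkSpec(
            node_dG={"A": 0.0, "B": -0.6, "C": 0.9},
            edges=[("A", "B"), ("B", "C"), ("A", "C")],
            noise_sigma=0.1,
            seed=5,
        )
        net = build_network(make_fep_network(spec), reference="A")
        flipped = FepNetwork(
            nodes=net.nodes,
            binding_edges=[(v, u, -g) for u, v, g in net.binding_edges],
            reference="A",
        )
        a = relative_dpkd(net)
        b = relative_dpkd(flipped)
        for node in a:
            assert a[node] == pytest.approx(b[node], abs=1e-10)

    def test_disconnected_node_excluded_with_warning(self):
        net = FepNetwork(
            nodes=["A", "B", "Z"], binding_edges=[("A", "B", 1.0)], reference="A"
        )
        with pytest.warns(UserWarning, match="Z"):
            result = relative_dpkd(net)
        assert "Z" not in result


class TestRestraintSensitivity:
    def test_identical_tables_zero_spread(self):
        table = {"A": 0.0, "B": -0.7}
        report = restraint_sensitivity({0.1: table, 1.0: dict(table), 10.0: dict(table)})
        assert (report["spread"] == 0).all()
        assert not report["flagged"].any()

    def test_deviant_ligand_flagged(self):
        report = restraint_sensitivity(
            {
                0.1: {"A": 0.0, "B": -0.7},
                1.0: {"A": 0.0, "B": -0.2},
            },
            flag_threshold=0.4,
        )
        row = report.set_index("ligand_id").loc["B"]
        assert row["spread"] == pytest.approx(0.5)
        assert bool(row["flagged"])

    def test_mean_spread_grows_with_jitter(self):
        rng = np.random.default_rng(3)
        means = []
        for sigma in (0.05, 0.2, 0.8):
            spreads = []
            for _ in range(50):
                base = {"A": 0.0, "B": -0.7, "C": 0.4}
                tables = {
                    fc: {lig: v + rng.normal(0, sigma) for lig, v in base.items()}
                    for fc in (0.1, 1.0, 10.0)
                }
                spreads.append(restraint_sensitivity(tables)["spread"].mean())
            means.append(np.mean(spreads))
        assert means[0] < means[1] < means[2]

    def test_single_level_raises(self):
        with pytest.raises(ValueError):
            restraint_sensitivity({1.0: {"A": 0.0}})


def test_edge_table_round_trip(tmp_path):
    edges = [
        FepEdge("5", "11", "complex", -1.1, ddG_reverse=1.05, force_constant=10.0),
        FepEdge("5", "11", "solvent", -0.2, ddG_reverse=0.21, force_constant=10.0),
        FepEdge("5", "7", "complex", 2.4, force_constant=0.1),
    ]
    path = tmp_path / "edges.tsv"
    write_edge_table(edges, path)
    back = read_edge_table(path)
    assert len(back) == 3
    assert back[0].ddG == pytest.approx(-1.1)
    assert back[0].ddG_reverse == pytest.approx(1.05)
    assert back[2].ddG_reverse is None
    assert back[2].force_constant == pytest.approx(0.1)
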