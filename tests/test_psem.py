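"""Piecewise SEM: spec validation, basis sets against a graph-theoretic
d-separation oracle, Fisher's C, standardisation, fitting and the
multigroup free/constrain machinery."""

import itertools

import networkx as nx
import numpy as np
import pytest

from hetstab import (
    basis_set,
    default_sem_spec,
    dsep_tests,
    fishers_c,
    fit_psem,
    model_simplify,
    multigroup,
    simulate_from_dag,
    standardise,
    validate_spec,
)
from hetstab.psem import DEFAULT_TRUE_SPC, SemSpec


def spec_of(edges, nodes=None, correlated=(), group=None, options=None):
    nodes = nodes or sorted({n for e in edges for n in e})
    return SemSpec(nodes=list(nodes), edges=list(edges),
                   correlated=list(correlated), group=group, options=options or {})


class TestValidateSpec:
    def test_chain_topological_order(self):
        spec = validate_spec(spec_of([("A", "B"), ("B", "C")]))
        assert spec.parents("C") == ["B"]
        assert spec.exogenous == {"A"}

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            validate_spec(spec_of([("A", "B"), ("B", "A")]))

    def test_unknown_node_and_duplicates_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            validate_spec(SemSpec(nodes=["A"], edges=[("A", "B")]))
        with pytest.raises(ValueError, match="duplicate"):
            validate_spec(spec_of([("A", "B"), ("A", "B")]))
        with pytest.raises(ValueError, match="self-loop"):
            validate_spec(SemSpec(nodes=["A"], edges=[("A", "A")]))

    def test_correlated_pair_cannot_be_directed_edge(self):
        with pytest.raises(ValueError, match="also a directed edge"):
            validate_spec(spec_of([("A", "B")], correlated=[("B", "A")]))

    def test_yaml_round_trip(self):
        spec = SemSpec.from_yaml(
            "nodes: [a, b, c]\npaths: ['a -> b', 'b -> c', 'a ~~ c']\n"
        )
        assert spec.edges == [("a", "b"), ("b", "c")]
        assert spec.correlated == [("a", "c")]


class TestBasisSet:
    def test_chain_single_claim(self):
        claims = basis_set(spec_of([("A", "B"), ("B", "C")]))
        assert len(claims) == 1
        assert (claims[0].x, claims[0].y, claims[0].cond) == ("A", "C", ("B",))

    def test_complete_dag_empty(self):
        claims = basis_set(spec_of([("A", "B"), ("A", "C"), ("B", "C")]))
        assert claims == []

    def test_collider_not_conditioned(self):
        claims = basis_set(spec_of([("A", "C"), ("B", "C")]))
        # A and B are both exogenous -> no claim at all
        assert claims == []
        # make B endogenous via D -> B: now (A,B) claim exists, C excluded
        claims = basis_set(spec_of([("A", "C"), ("B", "C"), ("D", "B")]))
        ab = [c for c in claims if {c.x, c.y} == {"A", "B"}]
        assert len(ab) == 1 and "C" not in ab[0].cond

    def test_correlated_pair_removed(self):
        claims = basis_set(spec_of([("A", "B"), ("B", "C")], correlated=[("A", "C")]))
        assert claims == []

    def test_oracle_all_small_dags(self):
        """Every claim is d-separated given its conditioning set, and every
        non-adjacent non-exogenous pair appears exactly once — verified by
        networkx d-separation over all DAGs on 4 nodes (every DAG is
        isomorphic to a subgraph of the triangular order)."""
        nodes = list("ABCD")
        possible = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        for mask in range(2 ** len(possible)):
            edges = [e for k, e in enumerate(possible) if mask >> k & 1]
            spec = spec_of(edges, nodes=nodes)
            g = spec.graph()
            exo = spec.exogenous
            claims = basis_set(spec)
            seen = {frozenset((c.x, c.y)) for c in claims}
            assert len(seen) == len(claims)
            for u, v in itertools.combinations(nodes, 2):
                adjacent = g.has_edge(u, v) or g.has_edge(v, u)
                expected = not adjacent and not (u in exo and v in exo)
                assert (frozenset((u, v)) in seen) == expected
            for c in claims:
                assert nx.is_d_separator(g, {c.x}, {c.y}, set(c.cond))


class TestFishersC:
    def test_all_ones_saturated(self):
        assert fishers_c([1.0, 1.0]) == (pytest.approx(0.0), 4, pytest.approx(1.0))
        assert fishers_c([]) == (0.0, 0, 1.0)

    def test_hand_value(self):
        c, df, p = fishers_c([0.5, 0.5])
        assert c == pytest.approx(-4 * np.log(0.5), abs=1e-4)
        assert c == pytest.approx(2.7726, abs=1e-4)
        assert df == 4

    def test_monotone_in_p(self, rng):
        ps = rng.uniform(0.05, 1, 6)
        c0, *_ = fishers_c(ps)
        ps[2] /= 10
        c1, *_ = fishers_c(ps)
        assert c1 > c0

    def test_floor_and_domain(self):
        c, df, p = fishers_c([1e-300])
        assert np.isfinite(c)
        with pytest.raises(ValueError):
            fishers_c([0.0])
        with pytest.raises(ValueError):
            fishers_c([1.5])


class TestStandardise:
    @pytest.mark.parametrize("b,sx,sy,out", [(2, 1, 2, 1.0), (0, 3, 5, 0.0), (-0.5, 2, 1, -1.0)])
    def test_values(self, b, sx, sy, out):
        assert standardise(b, sx, sy) == pytest.approx(out)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            standardise(1.0, 0.0, 1.0)


class TestSimulateFromDag:
    def test_population_spcs_and_unit_variance(self, study_design):
        spec = default_sem_spec()
        acc = {k: [] for k in DEFAULT_TRUE_SPC}
        for i in range(30):
            d = simulate_from_dag(spec, study_design, DEFAULT_TRUE_SPC, seed=100 + i)
            f = fit_psem(spec, d, dsep=False)
            for r in f.edges.itertuples():
                acc[f"{r.source}->{r.target}"].append(r.spc)
        for k, vals in acc.items():
            assert np.mean(vals) == pytest.approx(DEFAULT_TRUE_SPC[k], abs=0.08), k

    def test_deterministic(self, study_design):
        spec = default_sem_spec()
        a = simulate_from_dag(spec, study_design, DEFAULT_TRUE_SPC, seed=5)
        b = simulate_from_dag(spec, study_design, DEFAULT_TRUE_SPC, seed=5)
        assert a.equals(b)

    def test_overloaded_coefficients_rejected(self, study_design):
        spec = spec_of([("heterogeneity", "richness"), ("emersion", "richness")],
                       nodes=["heterogeneity", "emersion", "richness"])
        with pytest.raises(ValueError, match="residual variance"):
            simulate_from_dag(spec, study_design,
                              {"heterogeneity->richness": 0.9, "emersion->richness": 0.9}, seed=1)


class TestFitPsem:
    def test_single_edge_reduces_to_regression_slope(self, study_design, rng):
        spec = spec_of([("emersion", "richness")], nodes=["emersion", "richness"],
                       options={"richness": {"nesting": False}})
        d = study_design.copy()
        d["emersion"] = d.emersion_ratio
        d["richness"] = 2.0 * zscore_np(d.emersion.to_numpy()) + rng.normal(0, 1, len(d))
        f = fit_psem(spec, d, dsep=False)
        r = f.edges.iloc[0]
        # SPC equals Pearson correlation for a bivariate regression
        expect = np.corrcoef(d.emersion, d.richness)[0, 1]
        assert r.spc == pytest.approx(expect, abs=1e-10)

    def test_missing_node_column_aborts_named(self, study_design):
        spec = spec_of([("emersion", "missing_node")], nodes=["emersion", "missing_node"])
        with pytest.raises(ValueError, match="missing_node"):
            fit_psem(spec, study_design.assign(emersion=study_design.emersion_ratio))

    def test_dsep_power_detects_missing_link(self, study_design):
        """A strong real A->C link omitted from the spec is flagged by its
        d-sep claim in the vast majority of replicates."""
        full = spec_of([("heterogeneity", "richness"), ("richness", "asynchrony"),
                        ("heterogeneity", "asynchrony")],
                       nodes=["heterogeneity", "richness", "asynchrony"])
        truncated = spec_of([("heterogeneity", "richness"), ("richness", "asynchrony")],
                            nodes=["heterogeneity", "richness", "asynchrony"])
        hits = 0
        for i in range(40):
            d = simulate_from_dag(full, study_design,
                                  {"heterogeneity->richness": 0.4,
                                   "richness->asynchrony": 0.4,
                                   "heterogeneity->asynchrony": 0.5}, seed=300 + i)
            claims = dsep_tests(truncated, d)
            p = claims.loc[(claims.x == "asynchrony") | (claims.y == "asynchrony"), "p"].iloc[0]
            hits += p < 0.05
        assert hits / 40 > 0.9


class TestMultigroup:
    def test_single_group_reduces_to_plain_fit(self, study_design):
        spec = default_sem_spec()
        d = simulate_from_dag(spec, study_design, DEFAULT_TRUE_SPC, seed=9)
        d["zone"] = "only"
        mg = multigroup(spec, d, group="zone")
        plain = fit_psem(spec, d)
        a = mg.edges.set_index(["source", "target"]).spc
        b = plain.edges.set_index(["source", "target"]).spc
        assert np.allclose(a.sort_index(), b.sort_index(), atol=1e-9)

    def test_zone_varying_link_most_frequently_freed(self, study_design):
        """With only the heterogeneity->richness path varying by zone it is
        the most frequently freed edge, detected in most replicates."""
        from hetstab.psem import ZONE_VARYING_TRUE_SPC
        spec = default_sem_spec()
        freed_counts: dict = {}
        n_rep = 30
        for i in range(n_rep):
            d = simulate_from_dag(spec, study_design, ZONE_VARYING_TRUE_SPC, seed=400 + i)
            mg = multigroup(spec, d)
            for key in {(r.source, r.target) for r in mg.edges[mg.edges.free].itertuples()}:
                freed_counts[key] = freed_counts.get(key, 0) + 1
        top = max(freed_counts, key=freed_counts.get)
        assert top == ("heterogeneity", "richness")
        assert freed_counts[top] / n_rep > 0.7

    def test_small_group_dropped_with_warning(self, study_design):
        spec = default_sem_spec()
        d = simulate_from_dag(spec, study_design, DEFAULT_TRUE_SPC, seed=12)
        d.loc[d.index[:-4], "zone"] = np.where(
            d.emersion_ratio.iloc[:-4] > 0.5, "high", "low"
        )
        d.loc[d.index[-4:], "zone"] = "tiny"
        mg = multigroup(spec, d)
        assert any("tiny" in w for w in mg.warnings)
        assert "tiny" not in mg.groups


class TestModelSimplify:
    def test_no_cluster_variance_no_discrepancy(self, study_design):
        spec = default_sem_spec()
        d = simulate_from_dag(spec, study_design, DEFAULT_TRUE_SPC, seed=21,
                              vc_shares=(1e-9, 1e-9))
        plain, rep = model_simplify(spec, d)
        assert rep.delta.abs().max() < 0.1
        assert not rep.flagged.any()

    def test_flagging_contract(self, study_design):
        spec = default_sem_spec()
        d = simulate_from_dag(spec, study_design, DEFAULT_TRUE_SPC, seed=22)
        _, rep = model_simplify(spec, d, threshold=0.0001)
        expected = (rep.delta.abs() > 0.0001) | rep.sign_flip
        assert (rep.flagged == expected).all()


def zscore_np(v):
    return (v - v.mean()) / v.std(ddof=1)
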