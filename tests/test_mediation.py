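"""Natural effect decomposition: closed forms, identities, structural zeros."""

import numpy as np
import pytest

from lagnet import county_diabetes as cd
from lagnet.discrete import CPT, BinaryNetwork, binarize, estimate_cpts
from lagnet.mediation import effect_table, effects_frame, natural_effects, total_effect
from lagnet.network import TemporalDAG
from lagnet.panel import Node
from lagnet.synthetic import generate_panel, study_like_spec

from conftest import random_binary_network


def chain_xmy(p_x=0.4, m1=0.9, m0=0.2, y1=0.7, y0=0.1):
    """x -> m -> y with no direct x -> y edge."""
    x, m, y = Node("x", 2015), Node("m", 2016), Node("y", 2017)
    dag = TemporalDAG.from_edges([(x, m, 1.0, 1.0), (m, y, 1.0, 1.0)], outcome=y)
    cpts = {
        x: CPT(node=x, parents=(), table=np.array([p_x])),
        m: CPT(node=m, parents=(x,), table=np.array([m0, m1])),
        y: CPT(node=y, parents=(m,), table=np.array([y0, y1])),
    }
    return BinaryNetwork(dag=dag, cpts=cpts, alpha=0.0), x, m, y


class TestTotalEffect:
    def test_chain_is_difference_of_rows(self):
        net, x, m, y = chain_xmy()
        te = total_effect(net, x, m)
        assert te == pytest.approx(0.9 - 0.2, abs=1e-12)

    def test_no_path_gives_zero(self):
        net = random_binary_network(5, seed=2)
        # pick a node with no path to the outcome, if present
        import networkx as nx

        outcome = net.dag.outcome
        for n in net.nodes():
            if n != outcome and not nx.has_path(net.dag.graph, n, outcome):
                assert total_effect(net, n, outcome) == pytest.approx(0.0, abs=1e-12)
                break

    def test_matches_enumeration_on_random_networks(self):
        from lagnet.discrete import brute_force_query, mutilate

        rng = np.random.default_rng(0)
        for k in range(10):
            net = random_binary_network(int(rng.integers(4, 9)), seed=100 + k)
            outcome = net.dag.outcome
            exposure = net.nodes()[0]
            if exposure == outcome:
                continue
            te = total_effect(net, exposure, outcome)
            oracle = brute_force_query(
                mutilate(net, {exposure: 1}), outcome
            ) - brute_force_query(mutilate(net, {exposure: 0}), outcome)
            assert te == pytest.approx(oracle, abs=1e-12)


class TestNaturalEffects:
    def test_pure_chain_closed_form(self):
        net, x, m, y = chain_xmy()
        rep = natural_effects(net, x, y, [m])
        assert rep.natural_direct == pytest.approx(0.0, abs=1e-12)
        expected_nie = (0.9 - 0.2) * (0.7 - 0.1)
        assert rep.natural_indirect == pytest.approx(expected_nie, abs=1e-12)
        assert rep.total_effect == pytest.approx(expected_nie, abs=1e-12)

    def test_disconnected_mediator_gives_pure_direct_effect(self):
        x, m, y = Node("x", 2015), Node("m", 2015), Node("y", 2017)
        dag = TemporalDAG.from_edges(
            [(x, y, 1.0, 1.0)], outcome=y, extra_nodes=[m], prune_isolated=False
        )
        cpts = {
            x: CPT(node=x, parents=(), table=np.array([0.5])),
            m: CPT(node=m, parents=(), table=np.array([0.5])),
            y: CPT(node=y, parents=(x,), table=np.array([0.2, 0.9])),
        }
        net = BinaryNetwork(dag=dag, cpts=cpts, alpha=0.0)
        with pytest.warns(UserWarning, match="no .* path"):
            rep = natural_effects(net, x, y, [m])
        assert rep.natural_indirect == pytest.approx(0.0, abs=1e-12)
        assert rep.natural_direct == pytest.approx(0.7, abs=1e-12)
        assert rep.total_effect == pytest.approx(total_effect(net, x, y), abs=1e-12)

    def test_decomposition_identity_on_random_networks(self):
        """TE(nested) = NDE + NIE to 1e-10, mediators = outcome parents."""
        import warnings

        rng = np.random.default_rng(1)
        checked = 0
        k = 0
        while checked < 50:
            net = random_binary_network(int(rng.integers(4, 9)), seed=200 + k)
            k += 1
            outcome = net.dag.outcome
            parents = list(net.cpts[outcome].parents)
            candidates = [
                n for n in net.nodes() if n != outcome and n not in parents
                and n.time < outcome.time
            ]
            if not candidates:
                continue
            exposure = candidates[0]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = natural_effects(net, exposure, outcome, parents)
            assert rep.total_effect == pytest.approx(
                rep.natural_direct + rep.natural_indirect, abs=1e-10
            )
            # mediators cover all outcome parents here, so the nested total
            # must equal the interventional contrast as well
            assert rep.total_effect == pytest.approx(
                total_effect(net, exposure, outcome), abs=1e-10
            )
            checked += 1

    def test_antisymmetry_under_exposure_relabeling(self):
        net, x, m, y = chain_xmy()
        rep = natural_effects(net, x, y, [m])
        # relabel: swap the exposure's states by flipping its CPT and the
        # mediator's conditional rows
        cpts = dict(net.cpts)
        cpts[x] = CPT(node=x, parents=(), table=np.array([1 - 0.4]))
        cpts[m] = CPT(node=m, parents=(x,), table=np.array([0.9, 0.2]))
        flipped = BinaryNetwork(dag=net.dag, cpts=cpts, alpha=0.0)
        rep_f = natural_effects(flipped, x, y, [m])
        assert rep_f.total_effect == pytest.approx(-rep.total_effect, abs=1e-12)

    def test_per_mediator_sums_to_joint_for_single_mediator(self):
        net, x, m, y = chain_xmy()
        rep = natural_effects(net, x, y, [m], per_mediator=True)
        assert rep.per_mediator_indirect[m] == pytest.approx(
            rep.natural_indirect, abs=1e-12
        )


class TestEffectTable:
    @pytest.fixture(scope="class")
    def worked_example_net(self):
        panel, _ = generate_panel(study_like_spec(600, seed=21))
        dag = cd.network()
        return estimate_cpts(binarize(panel), dag, alpha=1.0)

    def test_five_variables_have_nonzero_nde(self, worked_example_net):
        reports = effect_table(worked_example_net)
        nonzero = {r.exposure.variable for r in reports if abs(r.natural_direct) > 1e-9}
        assert nonzero == {
            "diabetic", "african_american", "obese",
            "physically_inactive", "poor_fair_health",
        }

    def test_indirect_variables_have_exactly_zero_nde(self, worked_example_net):
        reports = effect_table(worked_example_net)
        for r in reports:
            if r.classification == "indirect":
                assert r.natural_direct == 0.0

    def test_identity_holds_for_every_row(self, worked_example_net):
        for r in effect_table(worked_example_net):
            assert r.total_effect == pytest.approx(
                r.natural_direct + r.natural_indirect, abs=1e-10
            )
            assert -1.0 <= r.total_effect <= 1.0

    def test_zero_edge_network_gives_all_zero_table(self):
        y = Node("y", 2017)
        dag = TemporalDAG.from_edges(
            [], outcome=y, extra_nodes=[Node("x", 2015)], prune_isolated=False
        )
        cpts = {
            y: CPT(node=y, parents=(), table=np.array([0.4])),
            Node("x", 2015): CPT(node=Node("x", 2015), parents=(), table=np.array([0.6])),
        }
        net = BinaryNetwork(dag=dag, cpts=cpts, alpha=0.0)
        reports = effect_table(net)
        assert reports
        for r in reports:
            assert r.total_effect == 0.0
            assert r.natural_direct == 0.0
            assert r.natural_indirect == 0.0

    def test_effects_frame_layout(self, worked_example_net):
        df = effects_frame(effect_table(worked_example_net, per_mediator=True))
        assert {"variable", "classification", "total_effect",
                "natural_direct", "natural_indirect"} <= set(df.columns)
        assert len(df) == len(cd.network().variables())  # one row per base variable
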