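"""Forward network generation and reverse route prediction."""

import pytest

from oglyco.grammar import parse, residue_count, validate_chemistry
from oglyco.simulator import (
    NetworkSizeError,
    SimulationConfig,
    format_log,
    forward_from_prediction,
    predict,
    simulate,
)

MUC7 = "[S3L4[f3][s6]Y6][[S3L4[f3][s6]Y6][S3L4[f3][s6]Y3]L3]VT"


class TestSimulate:
    def test_initiation_only_panel_closes_immediately(self):
        net = simulate(SimulationConfig(max_iterations=10,
                                        enabled_enzymes=frozenset({2})))
        assert set(net.nodes) == {"T", "VT"}
        assert len(net.edges) == 1
        assert net.closed_at == 2
        assert net.closure_iteration == 1

    def test_determinism(self):
        a = simulate(SimulationConfig(max_iterations=5))
        b = simulate(SimulationConfig(max_iterations=5))
        assert a.nodes == b.nodes
        assert a.edges == b.edges

    def test_every_edge_adds_one_residue(self, small_network):
        for r in small_network.edges:
            assert (residue_count(parse(r.product))
                    == residue_count(parse(r.substrate)) + 1)

    def test_network_is_a_dag(self, small_network):
        import networkx as nx

        assert nx.is_directed_acyclic_graph(
            nx.DiGraph((r.substrate, r.product) for r in small_network.edges))

    @pytest.mark.parametrize("limit", [0, 1, 2, 3])
    def test_glcnac_limit_closes_the_network(self, limit):
        net = simulate(SimulationConfig(max_iterations=60,
                                        glcnac_limit=limit))
        assert net.closed_at is not None
        from oglyco.grammar import glcnac_count

        assert all(glcnac_count(parse(g)) <= limit for g in net.glycans())

    def test_node_ceiling_guard(self):
        with pytest.raises(NetworkSizeError):
            simulate(SimulationConfig(max_iterations=9, max_nodes=100))

    def test_all_outputs_parse_and_are_feasible(self, glycan_pool):
        for g in glycan_pool:
            assert validate_chemistry(parse(g)) == []


class TestLog:
    def test_first_line_and_serials(self, small_network):
        lines = format_log(small_network)
        assert lines[0] == "1: T -- ppGalNAc-Ts --> VT (1)"
        serials = []
        seen = set()
        for line in lines:
            serial = int(line.rsplit("(", 1)[1].rstrip(")"))
            if serial not in seen:
                seen.add(serial)
                serials.append(serial)
        assert serials == sorted(serials)

    def test_every_logged_product_reparses(self, small_network):
        for line in format_log(small_network):
            product = line.split(" --> ")[1].rsplit(" (", 1)[0]
            parse(product)


class TestPredict:
    def test_tn_antigen(self):
        result = predict("VT")
        assert result.predictable
        assert result.iterations_used == 1
        assert result.enzymes_used == {2}

    def test_muc7_glycan_deconstruction(self):
        result = predict(MUC7)
        assert result.predictable
        assert result.iterations_used == 17
        assert result.enzymes_used == {1, 2, 5, 6, 7, 11, 16, 19, 20}

    def test_internally_fucosylated_chain_is_not_predictable(self):
        assert not predict("[L4Y3L4[f3]Y6][L3]VT").predictable

    def test_iterations_equal_residue_count_when_predictable(self):
        for ident in ("[S6][S3L3]VT", "[L4Y6][L3]VT", "[Y6][Y3]VT"):
            result = predict(ident)
            assert result.predictable
            assert result.iterations_used == residue_count(parse(ident))


class TestForwardFromPrediction:
    def test_tn(self):
        net = forward_from_prediction(predict("VT"))
        assert set(net.nodes) == {"T", "VT"}

    def test_muc7_network_contains_the_glycan(self):
        prediction = predict(MUC7)
        net = forward_from_prediction(prediction)
        assert MUC7 in net.nodes

    def test_unpredictable_raises(self):
        with pytest.raises(ValueError):
            forward_from_prediction(predict("[L4Y3L4[f3]Y6][L3]VT"))

    def test_validation_set_closure(self):
        """Each predictable reference glycan reappears in the forward
        network generated from its own predicted enzyme set."""
        from oglyco.experiments import load_validation_set

        for ident in load_validation_set()[:12]:
            prediction = predict(ident)
            if prediction.predictable:
                net = forward_from_prediction(prediction)
                assert ident in net.nodes


class TestConfigLoading:
    def test_from_dict_round_trip(self):
        cfg = SimulationConfig.from_dict({
            "max_iterations": 7,
            "glcnac_limit": 3,
            "enabled_enzymes": [1, 2, 6],
            "gcnt2_inhibition": "off",
            "rule4_type2": False,
        })
        assert cfg.max_iterations == 7
        assert cfg.glcnac_limit == 3
        assert cfg.enabled_enzymes == frozenset({1, 2, 6})
        assert cfg.panel_config.gcnt2_inhibition == "off"
        assert not cfg.panel_config.rule4_type2

    def test_from_json(self, tmp_path):
        path = tmp_path / "config.json"
        path.write_text('{"max_iterations": 4, "enabled_enzymes": [2]}')
        cfg = SimulationConfig.from_json(path)
        net = simulate(cfg)
        assert set(net.nodes) == {"T", "VT"}
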