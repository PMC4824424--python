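"""The enzyme panel: matching, application and exact reversibility."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from oglyco.enzymes import (
    PanelConfig,
    apply_forward,
    apply_reverse,
    default_panel,
    has_i_branch,
    match_sites,
    panel_by_id,
)
from oglyco.grammar import parse, residue_count, validate_chemistry

PANEL = panel_by_id()


class TestPanel:
    def test_twenty_five_rules_with_sequential_ids(self):
        panel = default_panel()
        assert [r.id for r in panel] == list(range(1, 26))

    def test_initiating_enzyme(self):
        rule = PANEL[2]
        assert rule.short_name == "ppGalNAc-Ts"
        assert rule.donor == "UDP-V"

    @pytest.mark.parametrize("rid, donor", [
        (1, "UDP-L"), (5, "UDP-Y"), (11, "GDP-f"), (17, "CMP-S"),
        (21, "PAP-s"), (25, "UDP-V"),
    ])
    def test_donors(self, rid, donor):
        assert PANEL[rid].donor == donor

    def test_sulfotransferase_adds_3_sulfate_to_type1_gal(self):
        assert apply_forward(PANEL[21], parse("[L3Y6][L3]VT")) == \
            {"[[s3]L3Y6][L3]VT"}


class TestMatching:
    def test_two_terminal_glcnacs_give_two_sites(self):
        # brute-force check: exactly the two leaves of the 3-residue tree
        sites = match_sites(PANEL[1], parse("[Y6][Y3]VT"))
        assert len(sites) == 2

    def test_core2_synthase_rejects_sialylated_core1(self):
        assert match_sites(PANEL[5], parse("[S3L3]VT")) == []

    def test_sialylation_tolerates_fucose_on_the_glcnac(self):
        sites = match_sites(PANEL[16], parse("[L4[f3]Y6][L3]VT"))
        assert len(sites) == 1

    def test_sulfate_never_blocks_matching(self):
        assert apply_forward(PANEL[1], parse("[[s6]Y3]VT")) == \
            {"[L4[s6]Y3]VT"}

    def test_i_branch_detection(self):
        assert has_i_branch(parse("[[Y6][L4Y3]L4Y3]VT"))
        assert not has_i_branch(parse("[Y6][Y3]VT"))


class TestForward:
    @pytest.mark.parametrize("rid, substrate, products", [
        (2, "T", {"VT"}),
        (17, "[S3L3]VT", {"[S6][S3L3]VT"}),
        (1, "[Y6][Y3]VT", {"[L4Y6][Y3]VT", "[Y6][L4Y3]VT"}),
        (6, "VT", {"[L3]VT"}),
        (5, "[L3]VT", {"[Y6][L3]VT"}),
        (19, "[Y6][L4Y3L3]VT", {"[Y6][[Y6][L4Y3]L3]VT"}),
        (15, "[Y6][L3]VT", {"[Y6][S3L3]VT"}),
        (14, "[Y3]VT", {"[S6][Y3]VT"}),
        (25, "[S3L4Y6][L3]VT", {"[S3[V4]L4Y6][L3]VT"}),
    ])
    def test_examples(self, rid, substrate, products):
        assert apply_forward(PANEL[rid], parse(substrate)) == products

    def test_each_product_adds_exactly_one_residue(self, glycan_pool):
        for g in glycan_pool[:120]:
            tree = parse(g)
            n = residue_count(tree)
            for rule in PANEL.values():
                for product in apply_forward(rule, tree):
                    assert residue_count(parse(product)) == n + 1

    def test_products_are_chemistry_valid(self, glycan_pool):
        for g in glycan_pool[:120]:
            tree = parse(g)
            for rule in PANEL.values():
                for product in apply_forward(rule, tree):
                    assert validate_chemistry(parse(product)) == []

    def test_poly_lacnac_blocked_below_new_i_branch(self):
        # the 6-branch made by the I-branching enzyme is not elongated
        g = parse("[Y6][[L4Y6][L4Y3]L3]VT")
        products = apply_forward(PANEL[10], g)
        assert products == {"[Y6][[L4Y6][Y3L4Y3]L3]VT"}


class TestReverse:
    @pytest.mark.parametrize("rid, product, precursors", [
        (2, "VT", {"T"}),
        (17, "[S6][S3L3]VT", {"[S3L3]VT"}),
        (1, "[L4Y6][Y3]VT", {"[Y6][Y3]VT"}),
        (20, "[L4[s6]Y3]VT", set()),  # sulfate removable only from bare GlcNAc
    ])
    def test_examples(self, rid, product, precursors):
        assert apply_reverse(PANEL[rid], parse(product)) == precursors

    def test_exact_inversion_on_reachable_structures(self, glycan_pool):
        """g in reverse(r, p) iff p in forward(r, g), across the panel."""
        for g in glycan_pool[:80]:
            tree = parse(g)
            for rule in PANEL.values():
                for product in apply_forward(rule, tree):
                    assert g in apply_reverse(rule, parse(product))
                for precursor in apply_reverse(rule, tree):
                    assert g in apply_forward(rule, parse(precursor))


def test_sulfotransferase_knockout_yields_no_sulfate():
    from oglyco.simulator import SimulationConfig, simulate

    net = simulate(SimulationConfig(
        max_iterations=5,
        enabled_enzymes=frozenset(range(1, 26)) - {20, 21, 22}))
    assert not any("s" in g for g in net.glycans())


@settings(max_examples=60, deadline=None)
@given(data=st.data())
def test_terminal_glcnac_sites_agree_with_exhaustive_scan(glycan_pool, data):
    """Sites of the terminal-GlcNAc rules equal a brute-force node scan."""
    g = data.draw(st.sampled_from(glycan_pool))
    rid, position = data.draw(st.sampled_from([(1, 4), (12, 3), (20, 6)]))
    tree = parse(g)
    expected = sum(
        1 for node in tree.walk()
        if node.code == "Y"
        and all(c.code == "s" for c in node.children)
        and position not in node.occupied_positions()
    )
    assert len(match_sites(PANEL[rid], tree)) == expected
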