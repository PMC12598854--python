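"""Disconnectivity graphs: dinfo parsing, superbasin construction against a
brute-force oracle, layout rules and rendering."""

import numpy as np
import pytest

from dridscape.disconnectivity import (DisconnectivityConfig, build_tree,
                                       layout_tree, parse_dinfo,
                                       read_order_parameter, render,
                                       superbasins)
from dridscape.network import KineticNetwork

from conftest import brute_force_superbasins, random_db_network


def toy_net(f, barriers):
    f = np.asarray(f, dtype=float)
    return KineticNetwork(free_energy=f, rates=np.zeros((f.size, f.size)),
                          barriers=dict(barriers), temperature=310.0)


@pytest.fixture
def three_minimum_net():
    # F = (0, 1, 0.4); barriers 1-2: 2.2, 2-3: 1.4 (1-based ids)
    return toy_net([0.0, 1.0, 0.4], {(0, 1): 2.2, (1, 2): 1.4})


# ---------------------------------------------------------------------------
# dinfo & order parameters
# ---------------------------------------------------------------------------

def test_parse_dinfo(tmp_path):
    p = tmp_path / "dinfo"
    p.write_text("DELTA 0.5\nFIRST 12\nLEVELS 25\nMINIMA min.data\nTS ts.data\n")
    cfg = parse_dinfo(p)
    assert (cfg.delta, cfg.first, cfg.levels) == (0.5, 12.0, 25)
    assert cfg.minima_path == "min.data" and cfg.ts_path == "ts.data"


def test_parse_dinfo_missing_keyword(tmp_path):
    p = tmp_path / "dinfo"
    p.write_text("DELTA 0.5\nFIRST 12\nMINIMA min.data\n")
    with pytest.raises(ValueError, match="TS"):
        parse_dinfo(p)


def test_parse_dinfo_unknown_keyword_warns(tmp_path):
    p = tmp_path / "dinfo"
    p.write_text("DELTA 0.5\nFIRST 3\nMINIMA m\nTS t\nFOO bar\n")
    with pytest.warns(UserWarning, match="FOO"):
        cfg = parse_dinfo(p)
    assert cfg.delta == 0.5
    assert cfg.levels == 7  # defaulted to ceil(FIRST/DELTA) + 1


def test_read_order_parameter(tmp_path):
    p = tmp_path / "op.txt"
    p.write_text("1.5\n2.5\n0.5\n\n")
    vals = read_order_parameter(p, 3)
    assert np.allclose(vals, [1.5, 2.5, 0.5])
    p.write_text("1.0\nbogus\n2.0\n")
    with pytest.raises(ValueError, match="line 2"):
        read_order_parameter(p, 3)
    p.write_text("1.0\n2.0\n")
    with pytest.raises(ValueError, match="3 minima"):
        read_order_parameter(p, 3)


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def test_build_tree_hand_example(three_minimum_net):
    cfg = DisconnectivityConfig(delta=0.5, first=2.5, levels=5)
    tree = build_tree(three_minimum_net, cfg)
    by_level = [{frozenset(n.members) for n in lev} for lev in tree.levels]
    assert by_level[0] == {frozenset({0, 1, 2})}                 # E = 2.5
    assert by_level[1] == {frozenset({0}), frozenset({1, 2})}    # E = 2.0
    assert by_level[2] == {frozenset({0}), frozenset({1, 2})}    # E = 1.5
    # at E = 1.0 minimum 1 (F=1.0) is no longer present: {1,2} has split
    assert by_level[3] == {frozenset({0}), frozenset({2})}
    assert sum(len(lev_nodes.terminals) for lev in tree.levels
               for lev_nodes in lev) == 3


def test_single_minimum_tree():
    tree = build_tree(toy_net([0.0], {}),
                      DisconnectivityConfig(delta=0.5, first=1.0, levels=2))
    assert len(tree.roots) == 1
    assert list(tree.leaves())[0][0] == 0


def test_huge_delta_merges_everything(three_minimum_net):
    cfg = DisconnectivityConfig(delta=100.0, first=50.0, levels=1)
    tree = build_tree(three_minimum_net, cfg)
    assert len(tree.roots) == 1
    assert tree.roots[0].members == frozenset({0, 1, 2})


def test_first_below_global_minimum_is_an_error(three_minimum_net):
    with pytest.raises(ValueError, match="FIRST"):
        build_tree(three_minimum_net,
                   DisconnectivityConfig(delta=0.5, first=-1.0, levels=3))


def test_superbasins_match_brute_force_oracle():
    """Union-find equals all-pairs max-barrier path search on random nets."""
    for seed in range(40):
        net = random_db_network(np.random.default_rng(seed).integers(3, 13),
                                seed=seed, extra_edges=3)
        f, edges = net.free_energy, net.barriers
        for threshold in np.linspace(f.min() + 0.1, max(edges.values()) + 1, 7):
            got = set(superbasins(f, edges, float(threshold)))
            expected = brute_force_superbasins(f, edges, float(threshold))
            assert got == expected, (seed, threshold)


def test_basin_nesting_is_monotone():
    for seed in range(15):
        net = random_db_network(10, seed=seed, extra_edges=4)
        first = max(net.barriers.values()) + 0.3
        cfg = DisconnectivityConfig(delta=0.4, first=first,
                                    levels=int(first / 0.4) + 1)
        tree = build_tree(net, cfg)
        for lev in tree.levels[1:]:
            for node in lev:
                assert node.parent is not None
                assert node.members <= node.parent.members
        n_leaves = sum(len(n.terminals) for lev in tree.levels for n in lev)
        assert n_leaves == net.n_states


def test_suspect_barriers_raised_for_merging_only():
    # barrier below the higher minimum: merging happens just above that minimum
    net = toy_net([0.0, 1.0], {(0, 1): 0.5})
    cfg = DisconnectivityConfig(delta=0.25, first=1.5, levels=6)
    tree = build_tree(net, cfg)
    top = {frozenset(n.members) for n in tree.levels[0]}
    assert top == {frozenset({0, 1})}
    # below F=1.0 the pair cannot be merged (minimum 1 absent)
    lower = [lev for lev, thr in zip(tree.levels, tree.thresholds) if thr <= 1.0]
    for lev in lower:
        for node in lev:
            assert node.members == frozenset({0})


# ---------------------------------------------------------------------------
# layout & rendering
# ---------------------------------------------------------------------------

def test_layout_centers_lowest_minimum(three_minimum_net):
    cfg = DisconnectivityConfig(delta=0.5, first=2.5, levels=5)
    tree = build_tree(three_minimum_net, cfg)
    pos = layout_tree(tree)
    assert len(pos) == 3
    assert len(set(pos.values())) == 3  # no two leaves share a position
    # within the {1, 2} funnel the lower minimum 2 sits closer to the
    # funnel's center than minimum 1
    funnel = next(n for lev in tree.levels for n in lev
                  if n.members == frozenset({1, 2}) and len(n.children) + len(n.terminals) > 1)
    center = n_center = funnel.x
    assert abs(pos[2] - n_center) <= abs(pos[1] - n_center)
    # determinism
    pos2 = layout_tree(build_tree(three_minimum_net, cfg))
    assert pos == pos2


def test_symmetric_two_leaf_tree_is_mirrored():
    net = toy_net([0.0, 0.0], {(0, 1): 1.0})
    tree = build_tree(net, DisconnectivityConfig(delta=0.5, first=1.5, levels=4))
    pos = layout_tree(tree)
    assert pos[0] + pos[1] == pytest.approx(1.0)


def test_render_svg(tmp_path, three_minimum_net):
    cfg = DisconnectivityConfig(delta=0.5, first=2.5, levels=5)
    tree = build_tree(three_minimum_net, cfg)
    layout = layout_tree(tree)
    out = render(tree, layout, coloring=np.array([0.0, 1.0, 2.0]),
                 label_lowest=2, path=tmp_path / "tree.svg")
    text = out.read_text()
    assert "<svg" in text
    # labels of the two lowest minima (ids 1 and 3, 1-based) are present
    assert ">1<" in text.replace(" ", "") or "1" in text
    with pytest.raises(ValueError, match="2 entries"):
        render(tree, layout, coloring=np.array([0.0, 1.0]), path=tmp_path / "t2.svg")
    # constant order parameter renders fine
    render(tree, layout, coloring=np.zeros(3), path=tmp_path / "t3.svg")
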