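"""Clash arithmetic, neighbour-search exactness, invariances."""
import numpy as np
import pytest

import ribograft as rg
from ribograft.clash_scoring import (ClashContext, pair_clash, score_graft,
                                     score_duplex)
from ribograft.hydroxyl_grafting import graft_duplex
from ribograft.structure_io import (AtomRecord, Residue, StructureModel,
                                    assign_radii)
from conftest import random_rotation


@pytest.mark.parametrize("ra,rb,d,expect", [
    (1.52, 1.70, 2.50, 0.72),     # O vs C closer than contact
    (1.52, 1.70, 3.22, 0.0),      # exactly at contact
    (1.52, 1.70, 5.0, 0.0),       # far apart
    (1.52, 1.52, 0.0, 3.04),      # coincident atoms
])
def test_pair_clash_arithmetic(ra, rb, d, expect):
    assert pair_clash(ra, [0, 0, 0], rb, [d, 0, 0]) == pytest.approx(expect)


def test_naked_duplex_has_zero_protein_clash(duplex_a):
    tbl = score_duplex(duplex_a, duplex_a.model)
    assert tbl["max_protein_s1"].max() == 0.0
    assert tbl["max_protein_s2"].max() == 0.0
    assert (tbl["cum_s1"] >= tbl["max_s1"]).all()


def _random_protein_cloud(rng, n, spread=25.0):
    model = StructureModel(source_id="cloud")
    res = Residue("P", 1, "GLY")
    res.atoms = [AtomRecord(f"C{i}", "C", rng.uniform(-spread, spread, 3))
                 for i in range(n)]
    res.category = "protein"
    model.add_residue(res)
    return model


@pytest.mark.parametrize("n_atoms", [500, 5000])
def test_neighbour_search_equals_bruteforce(n_atoms, duplex_a):
    """KD-tree scoring must equal the O(N^2) scan exactly."""
    rng = np.random.default_rng(n_atoms)
    model = duplex_a.model.copy()
    cloud = _random_protein_cloud(rng, n_atoms)
    for res in cloud.residues():
        model.add_residue(res)
    assign_radii(model)
    duplex = rg.pair_bases(model)
    grafts = graft_duplex(duplex).results
    ctx = ClashContext(model)
    for g in grafts[::3]:
        fast = score_graft(g, model, context=ctx)
        slow = score_graft(g, model, context=ctx, brute_force=True)
        assert fast.max_clash == slow.max_clash
        assert fast.cumulative_clash == slow.cumulative_clash
        assert fast.max_clash_protein == slow.max_clash_protein
        assert fast.cumulative_nucleic == slow.cumulative_nucleic


def test_monotone_in_probe_approach():
    """Moving the probe closer along the contact ray never decreases the
    maximal clash."""
    model = rg.build_fiber_duplex("GTAGGACCATC", "A")
    last = -1.0
    for clash in (0.0, 0.2, 0.5, 0.8, 1.1):
        pm = rg.place_probes(model, [rg.ProbeSpec(index=5,
                                                  intended_clash=clash)])
        assign_radii(pm)
        duplex = rg.pair_bases(pm)
        tbl = score_duplex(duplex, pm)
        val = tbl.loc[5, "max_protein_s1"]
        assert val >= last
        last = val


def test_rigid_motion_invariance(duplex_a):
    rng = np.random.default_rng(2)
    tbl1 = score_duplex(duplex_a, duplex_a.model)
    moved = duplex_a.model.transformed(random_rotation(rng),
                                      rng.normal(size=3) * 40)
    duplex2 = rg.pair_bases(moved)
    tbl2 = score_duplex(duplex2, moved)
    np.testing.assert_allclose(tbl1["max_s1"], tbl2["max_s1"], atol=1e-9)
    np.testing.assert_allclose(tbl1["cum_s2"], tbl2["cum_s2"], atol=1e-9)


def test_threshold_flag_consistency(duplex_a):
    model = rg.build_fiber_duplex("GTAGGACCATC", "A")
    pm = rg.place_probes(model, [rg.ProbeSpec(index=5, intended_clash=1.2)])
    assign_radii(pm)
    duplex = rg.pair_bases(pm)
    tbl = score_duplex(duplex, pm)
    for _, row in tbl.iterrows():
        worst = np.nanmax([row["max_s1"], row["max_s2"]])
        assert bool(row["above_threshold"]) == (worst > 1.1)


def test_strand_average_is_mean_of_single_strands(duplex_a):
    both = score_duplex(duplex_a, duplex_a.model)
    expected = np.nanmean(np.vstack([both["max_s1"], both["max_s2"]]), axis=0)
    np.testing.assert_allclose(both["max_mean"], expected, atol=1e-12)


def test_palindromic_probe_field_symmetric():
    """In a symmetric environment the two strands score identically."""
    model = rg.build_fiber_duplex("GGGACCGGTCCC", "A")   # palindrome
    assign_radii(model)
    duplex = rg.pair_bases(model)
    tbl = score_duplex(duplex, model)
    np.testing.assert_allclose(tbl["max_s1"], tbl["max_s2"][::-1], atol=1e-6)
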