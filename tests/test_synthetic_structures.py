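"""The synthetic generator: ground truth, endpoints, probes, determinism."""
import numpy as np
import pytest

import ribograft as rg
from ribograft.synthetic_structures import (FiberSpec, ProbeSpec,
                                            ProbePlacementError,
                                            SequenceError,
                                            build_fiber_duplex,
                                            interpolate_conformation,
                                            place_probes)


def test_b_build_matches_spec_twist(duplex_b):
    df = rg.analyze_duplex(duplex_b)
    assert df["helical_twist"].mean() == pytest.approx(36.0, abs=0.01)
    assert df["helical_rise"].mean() == pytest.approx(3.375, abs=0.001)


def test_hybrid_strands_classify():
    model = build_fiber_duplex("GUAGGACCAUG", "A", hybrid="strand1_rna")
    cats = {c: [r.category for r in model.chains[c]] for c in "AB"}
    assert set(cats["A"]) == {"RNA"}
    assert set(cats["B"]) == {"DNA"}
    assert all(r.comp_id in ("A", "C", "G", "U") for r in model.chains["A"])


@pytest.mark.parametrize("bad", ["G", "", "GXT", "GUT"])
def test_invalid_sequences_raise(bad):
    with pytest.raises(SequenceError):
        build_fiber_duplex(bad, "B")


def test_bad_helical_parameters_raise():
    with pytest.raises(SequenceError):
        build_fiber_duplex("GTAG", FiberSpec(form="B", rise=-1.0))
    with pytest.raises(SequenceError):
        build_fiber_duplex("GTAG", FiberSpec(form="B", twist=75.0))


def test_interpolation_endpoints_identical():
    seq = "GTAGGACCATC"
    for t, form in ((0.0, "B"), (1.0, "A")):
        direct = build_fiber_duplex(seq, form)
        interp = interpolate_conformation("A", "B", t, seq)
        assert interp.n_atoms == direct.n_atoms
        for (_, a1), (_, a2) in zip(direct.atoms(), interp.atoms()):
            np.testing.assert_array_equal(a1.position, a2.position)


def test_interpolation_midpoint_between_endpoints():
    seq = "GTAGGACCATC"
    zp = {}
    for key, t in (("B", 0.0), ("mid", 0.5), ("A", 1.0)):
        model = interpolate_conformation("A", "B", t, seq)
        df = rg.analyze_duplex(rg.pair_bases(model))
        zp[key] = df["zp"][3:7].mean()
    assert zp["B"] < zp["mid"] < zp["A"]


def test_out_of_range_t_raises():
    with pytest.raises(ValueError):
        interpolate_conformation("A", "B", 1.5, "GTAG")


def test_determinism_bit_identical():
    m1 = build_fiber_duplex("GTAGGACCATC", "A")
    m2 = build_fiber_duplex("GTAGGACCATC", "A")
    for (_, a1), (_, a2) in zip(m1.atoms(), m2.atoms()):
        np.testing.assert_array_equal(a1.position, a2.position)
    p = [ProbeSpec(index=4, intended_clash=0.5)]
    pm1 = place_probes(m1, p, seed=3)
    pm2 = place_probes(m2, p, seed=3)
    x1 = [a.position for _, a in pm1.atoms()]
    x2 = [a.position for _, a in pm2.atoms()]
    assert all(np.array_equal(u, v) for u, v in zip(x1, x2))


def test_generator_output_passes_io_and_pairing(tmp_path):
    model = build_fiber_duplex("GTAGGACCATC", "A", hybrid="strand2_rna")
    path = tmp_path / "hyb.pdb"
    rg.write_structure(model, path)
    again = rg.read_structure(path)
    duplex = rg.pair_bases(again)
    assert len(duplex) == 11


class TestProbes:
    def test_clash_free_probe_scores_zero(self):
        model = build_fiber_duplex("GTAGGACCATC", "A")
        pm = place_probes(model, [ProbeSpec(index=5, intended_clash=0.0,
                                            margin=0.5)])
        rg.assign_radii(pm)
        duplex = rg.pair_bases(pm)
        tbl = rg.score_duplex(duplex, pm)
        assert tbl["max_protein_s1"].max() == pytest.approx(0.0, abs=1e-12)

    def test_intended_clash_recovered_exactly(self):
        model = build_fiber_duplex("GTAGGACCATC", "A")
        pm = place_probes(model, [ProbeSpec(index=5, intended_clash=0.7)])
        rg.assign_radii(pm)
        duplex = rg.pair_bases(pm)
        tbl = rg.score_duplex(duplex, pm)
        assert tbl.loc[5, "max_protein_s1"] == pytest.approx(0.7, abs=1e-6)

    def test_above_threshold_flagged(self):
        model = build_fiber_duplex("GTAGGACCATC", "A")
        pm = place_probes(model, [ProbeSpec(index=5, intended_clash=1.2)])
        rg.assign_radii(pm)
        duplex = rg.pair_bases(pm)
        tbl = rg.score_duplex(duplex, pm)
        assert tbl.loc[5, "max_protein_s1"] == pytest.approx(1.2, abs=1e-6)
        assert bool(tbl.loc[5, "above_threshold"])

    def test_probe_chain_is_protein_category(self):
        model = build_fiber_duplex("GTAGGACCATC", "A")
        pm = place_probes(model, [ProbeSpec(index=2, intended_clash=0.3)])
        assert pm.chains["X"][0].category == "protein"

    def test_conflicting_probe_placement_errors(self):
        model = build_fiber_duplex("GTAGGACCATC", "A")
        with pytest.raises(ProbePlacementError):
            place_probes(model, [ProbeSpec(index=5, intended_clash=2.5),
                                 ProbeSpec(index=5, intended_clash=0.1)])
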