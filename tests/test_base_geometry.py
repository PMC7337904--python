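"""Superposition, base frames, step parameters, Zp, puckers."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ribograft as rg
from ribograft import base_geometry as bg
from ribograft.synthetic_structures import FiberSpec, build_fiber_duplex
from conftest import random_rotation


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        R, t, rmsd = bg.superpose(pts, pts)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0.0, atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(8, 3))
        R0 = random_rotation(rng)
        t0 = rng.normal(size=3) * 10
        mobile = pts @ R0.T + t0
        R, t, rmsd = bg.superpose(pts, mobile)
        np.testing.assert_allclose(R, R0, atol=1e-6)
        np.testing.assert_allclose(t, t0, atol=1e-6)
        assert rmsd < 1e-8

    def test_mirror_gives_proper_rotation_with_residual(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        R, t, rmsd = bg.superpose(pts, mirrored)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_collinear_raises(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(bg.DegenerateFitError):
            bg.superpose(pts, pts)


class TestBaseFrames:
    def test_template_at_known_pose_recovered(self):
        tmpl = bg.load_templates()["bases"]["G"]
        rng = np.random.default_rng(11)
        R0, t0 = random_rotation(rng), rng.normal(size=3) * 5
        from ribograft.structure_io import Residue, AtomRecord
        res = Residue("A", 1, "DG")
        res.atoms = [AtomRecord(n, n[0], R0 @ np.array(v) + t0)
                     for n, v in tmpl.items()]
        frame = bg.fit_base_frame(res)
        np.testing.assert_allclose(frame.axes, R0, atol=1e-6)
        np.testing.assert_allclose(frame.origin, t0, atol=1e-6)
        assert frame.rmsd < 1e-8

    def test_wc_pair_frames_antialigned(self, duplex_b):
        for pair in duplex_b.pairs:
            assert np.dot(pair.frame_i.z, pair.frame_j.z) < 0

    def test_missing_ring_atoms_error_names_them(self, duplex_b):
        res = duplex_b.pairs[2].res_i    # an adenine
        stripped = type(res)(res.chain_id, res.seq_id, res.comp_id)
        stripped.atoms = [a for a in res.atoms if a.name not in ("N9", "C8")]
        with pytest.raises(bg.IncompleteBaseError, match="N9"):
            bg.fit_base_frame(stripped)


class TestStepRoundTrip:
    @given(twist=st.floats(25.0, 40.0), rise=st.floats(2.3, 3.6),
           roll=st.floats(-5.0, 15.0), tilt=st.floats(-4.0, 4.0),
           slide=st.floats(-1.5, 1.5), shift=st.floats(-1.0, 1.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_analyze_inverts_compose(self, twist, rise, roll, tilt, slide, shift):
        params = bg.StepParameters(shift=shift, slide=slide, rise=rise,
                                   tilt=tilt, roll=roll, twist=twist)
        f1 = bg.BaseFrame(np.zeros(3), np.eye(3))
        f2 = bg.compose_step(f1, params)
        got = bg.step_parameters(f1, f2)
        for name in ("shift", "slide", "rise"):
            assert getattr(got, name) == pytest.approx(getattr(params, name),
                                                       abs=0.05)
        for name in ("tilt", "roll", "twist"):
            assert getattr(got, name) == pytest.approx(getattr(params, name),
                                                       abs=0.1)

    def test_full_generator_roundtrip(self):
        """Building a duplex from explicit steps and re-analyzing recovers
        them through the whole atom-level pipeline."""
        steps = [bg.StepParameters(shift=0.2, slide=-0.5, rise=3.2, tilt=1.0,
                                   roll=8.0, twist=33.0) for _ in range(7)]
        spec = FiberSpec(form="custom", steps=steps, sugar_form="B")
        model = build_fiber_duplex("GTAGGACC", spec)
        duplex = rg.pair_bases(model)
        df = rg.analyze_duplex(duplex)
        for name in ("shift", "slide", "rise"):
            np.testing.assert_allclose(df[name], getattr(steps[0], name),
                                       atol=0.05)
        for name in ("tilt", "roll", "twist"):
            np.testing.assert_allclose(df[name], getattr(steps[0], name),
                                       atol=0.1)

    def test_coincident_frames_raise(self):
        f = bg.BaseFrame(np.zeros(3), np.eye(3))
        with pytest.raises(bg.GeometryError):
            bg.step_parameters(f, f)


class TestHelicalParameters:
    def test_fiber_helical_twist_rise_recovered(self, duplex_a):
        df = rg.analyze_duplex(duplex_a)
        hel = duplex_a.model.provenance["helical"]
        np.testing.assert_allclose(df["helical_twist"], hel["twist"], atol=0.01)
        np.testing.assert_allclose(df["helical_rise"], hel["rise"], atol=0.001)
        np.testing.assert_allclose(df["x_displacement"], hel["xdisp"], atol=0.02)
        np.testing.assert_allclose(df["inclination"], hel["inclination"],
                                   atol=0.1)

    def test_strand_reversal_symmetry(self, duplex_b):
        """Reading the duplex from the other strand flips shift/tilt signs
        and preserves slide, rise, roll, twist."""
        fwd = rg.analyze_duplex(duplex_b)
        rev = rg.analyze_duplex(duplex_b.reversed())
        rev = rev.iloc[::-1].reset_index(drop=True)
        np.testing.assert_allclose(rev["shift"], -fwd["shift"], atol=1e-6)
        np.testing.assert_allclose(rev["tilt"], -fwd["tilt"], atol=1e-6)
        for name in ("slide", "rise", "roll", "twist"):
            np.testing.assert_allclose(rev[name], fwd[name], atol=1e-6)


class TestZpClassification:
    def test_ideal_forms_classify_correctly(self, duplex_a, duplex_b):
        dfa = rg.analyze_duplex(duplex_a)
        dfb = rg.analyze_duplex(duplex_b)
        assert (dfa["classification"] == "A").all()
        assert (dfb["classification"] == "B").all()
        assert dfa["zp"].min() > 1.5
        assert dfb["zp"].max() < 0.5

    def test_all_dinucleotide_steps_classify(self):
        """Every one of the 10 distinct dinucleotide step types classifies
        A on the ideal A build and B on the ideal B build."""
        seq = "AATTACAGATCCGGGCC"    # contains all 10 unique step types
        for form, want in (("A", "A"), ("B", "B")):
            model = build_fiber_duplex(seq, form)
            df = rg.analyze_duplex(rg.pair_bases(model))
            assert (df["classification"] == want).all()

    def test_zp_monotone_along_interpolation(self):
        from ribograft.synthetic_structures import interpolate_conformation
        zps = []
        for t in np.linspace(0.0, 1.0, 6):
            model = interpolate_conformation("A", "B", t, "GTAGGACCATC")
            df = rg.analyze_duplex(rg.pair_bases(model))
            zps.append(df["zp"][2:-2].mean())
        assert all(b >= a - 1e-6 for a, b in zip(zps, zps[1:]))


class TestPseudorotation:
    def test_a_and_b_templates(self, duplex_a, duplex_b):
        pa = bg.sugar_pucker(duplex_a.pairs[5].res_i)
        pb = bg.sugar_pucker(duplex_b.pairs[5].res_i)
        assert 0.0 <= pa.phase < 36.0 and pa.conformer == "C3'-endo"
        assert 144.0 <= pb.phase < 180.0 and pb.conformer == "C2'-endo"

    def test_planar_ring_undefined(self):
        with pytest.raises(bg.UndefinedPuckerError):
            bg.pseudorotation([0.0, 0.0, 0.0, 0.0, 0.0])

    def test_synthetic_phase_recovered(self):
        """Torsions generated from the pseudorotation formula invert."""
        for p0 in (18.0, 90.0, 162.0, 250.0):
            nus = [38.0 * np.cos(np.radians(p0 + 144.0 * (j - 2)))
                   for j in range(5)]
            res = bg.pseudorotation(nus)
            assert res.phase == pytest.approx(p0, abs=1e-9)
            assert res.amplitude == pytest.approx(38.0, abs=1e-9)


class TestDisplacement:
    def test_calibrated_definition_on_ideal_forms(self, long_duplex_a,
                                                  long_duplex_b):
        da = rg.base_pair_displacement(long_duplex_a)["mean"]
        db = rg.base_pair_displacement(long_duplex_b)["mean"]
        assert da == pytest.approx(6.9, abs=0.3)
        assert da > db      # A-form pairs sit far off the axis
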