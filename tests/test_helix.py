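"""Base frames, CEHS parameter algebra and groove widths."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from puckerfit import helix as hx


def random_frame(rng):
    return hx.BaseFrame(
        origin=rng.normal(size=3) * 5.0,
        axes=Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix(),
    )


class TestBaseFrame:
    def test_planted_transform_recovered_exactly(self, rng):
        R = Rotation.random(random_state=4).as_matrix()
        t = np.array([3.0, -2.0, 7.0])
        atoms = {n: R @ np.array(c) + t for n, c in hx.STANDARD_BASES["G"].items()}
        f = hx.base_frame(atoms, "DG")
        assert np.allclose(f.axes, R, atol=1e-9)
        assert np.allclose(f.origin, t, atol=1e-9)

    def test_perturbed_atoms_close_to_planted(self, rng):
        R = Rotation.random(random_state=9).as_matrix()
        t = np.array([-1.0, 4.0, 2.0])
        atoms = {
            n: R @ np.array(c) + t + rng.normal(0, 0.01, 3)
            for n, c in hx.STANDARD_BASES["C"].items()
        }
        f = hx.base_frame(atoms, "DC")
        dR = Rotation.from_matrix(f.axes @ R.T).magnitude()
        assert math.degrees(dR) < 1.0
        assert np.linalg.norm(f.origin - t) < 0.05

    def test_purine_and_pyrimidine_atom_sets(self):
        for resname in ("DA", "DG", "DC", "DT"):
            base = resname[1]
            atoms = {n: np.array(c) for n, c in hx.STANDARD_BASES[base].items()}
            f = hx.base_frame(atoms, resname)
            assert np.allclose(f.axes, np.eye(3), atol=1e-9)

    def test_too_few_atoms_raises(self):
        atoms = {n: np.array(c) for n, c in list(hx.STANDARD_BASES["A"].items())[:3]}
        with pytest.raises(ValueError, match=">=3"):
            hx.base_frame({"N9": atoms.get("N9", np.zeros(3))}, "DA")


class TestPairStepParameters:
    def test_coincident_frames_are_zero(self):
        f = hx.BaseFrame(origin=np.array([1.0, 2.0, 3.0]), axes=np.eye(3))
        p = hx.pair_parameters(f, f)
        assert all(
            getattr(p, k) == pytest.approx(0.0, abs=1e-9)
            for k in ("shear", "stretch", "stagger", "buckle", "propeller", "opening")
        )
        s = hx.step_parameters(f, f)
        assert all(
            getattr(s, k) == pytest.approx(0.0, abs=1e-9)
            for k in ("shift", "slide", "rise", "tilt", "roll", "twist")
        )

    def test_pure_twist_rise_step(self):
        f1 = hx.BaseFrame(origin=np.zeros(3), axes=np.eye(3))
        f2 = hx.BaseFrame(
            origin=np.array([0.0, 0.0, 3.4]), axes=hx._rot([0, 0, 1], 36.0)
        )
        s = hx.step_parameters(f1, f2)
        assert s.twist == pytest.approx(36.0, abs=1e-9)
        assert s.rise == pytest.approx(3.4, abs=1e-9)
        for k in ("shift", "slide", "tilt", "roll"):
            assert getattr(s, k) == pytest.approx(0.0, abs=1e-9)
        h = hx.helical_parameters(f1, f2)
        assert h.htwist == pytest.approx(36.0, abs=1e-9)
        assert h.hrise == pytest.approx(3.4, abs=1e-9)
        assert h.x_displacement == pytest.approx(0.0, abs=1e-9)
        assert h.inclination == pytest.approx(0.0, abs=1e-9)

    def test_rebuild_oracle_random_steps(self, rng):
        for _ in range(25):
            f1 = random_frame(rng)
            trans = rng.normal(size=3) * 2
            rots = rng.normal(size=3) * np.array([8, 8, 25])
            f2 = hx.params_to_frames(f1, trans, rots)
            t2, r2 = hx.frames_to_params(f1, f2)
            assert np.allclose(t2, trans, atol=1e-9)
            assert np.allclose(r2, rots, atol=1e-9)
            # idempotence: frames -> params -> frames -> params
            f2b = hx.params_to_frames(f1, t2, r2)
            t3, r3 = hx.frames_to_params(f1, f2b)
            assert np.allclose(t3, t2, atol=1e-9) and np.allclose(r3, r2, atol=1e-9)

    def test_rigid_body_invariance(self, rng):
        f1, f2 = random_frame(rng), random_frame(rng)
        R = Rotation.random(random_state=12).as_matrix()
        t = rng.normal(size=3) * 8
        g1 = hx.BaseFrame(origin=R @ f1.origin + t, axes=R @ f1.axes)
        g2 = hx.BaseFrame(origin=R @ f2.origin + t, axes=R @ f2.axes)
        s0, s1 = hx.step_parameters(f1, f2), hx.step_parameters(g1, g2)
        for k in ("shift", "slide", "rise", "tilt", "roll", "twist"):
            assert getattr(s1, k) == pytest.approx(getattr(s0, k), abs=1e-9)
        h0, h1 = hx.helical_parameters(f1, f2), hx.helical_parameters(g1, g2)
        for k in ("x_displacement", "y_displacement", "hrise", "inclination", "tip", "htwist"):
            assert getattr(h1, k) == pytest.approx(getattr(h0, k), abs=1e-9)

    def test_strand_reversal_antisymmetry(self, rng):
        f1 = random_frame(rng)
        f2 = hx.params_to_frames(f1, [0.5, -0.3, 3.3], [3.0, 5.0, 34.0])
        fwd = hx.step_parameters(f1, f2)
        rev = hx.step_parameters(hx.flip_frame(f2), hx.flip_frame(f1))
        assert rev.shift == pytest.approx(-fwd.shift, abs=1e-9)
        assert rev.tilt == pytest.approx(-fwd.tilt, abs=1e-9)
        assert rev.slide == pytest.approx(fwd.slide, abs=1e-9)
        assert rev.rise == pytest.approx(fwd.rise, abs=1e-9)
        assert rev.roll == pytest.approx(fwd.roll, abs=1e-9)
        assert rev.twist == pytest.approx(fwd.twist, abs=1e-9)
        hf = hx.helical_parameters(f1, f2)
        hr = hx.helical_parameters(hx.flip_frame(f2), hx.flip_frame(f1))
        assert hr.tip == pytest.approx(-hf.tip, abs=1e-9)
        assert hr.inclination == pytest.approx(hf.inclination, abs=1e-9)
        assert hr.htwist == pytest.approx(hf.htwist, abs=1e-9)

    def test_helical_round_trip_from_planted_parameters(self):
        frames = hx.helical_frames(
            4, htwist=33.0, hrise=2.9, inclination=15.0, tip=-3.0,
            x_displacement=-4.0, y_displacement=0.7,
        )
        for a, b in zip(frames[:-1], frames[1:]):
            h = hx.helical_parameters(a, b)
            assert h.htwist == pytest.approx(33.0, abs=1e-9)
            assert h.hrise == pytest.approx(2.9, abs=1e-9)
            assert h.inclination == pytest.approx(15.0, abs=1e-9)
            assert h.tip == pytest.approx(-3.0, abs=1e-9)
            assert h.x_displacement == pytest.approx(-4.0, abs=1e-9)
            assert h.y_displacement == pytest.approx(0.7, abs=1e-9)


class TestGrooveWidths:
    def test_cylinder_closed_form(self):
        # phosphates on a uniform cylinder: cross-strand distances have a
        # closed chord form, independent of level
        R, omega, h, n = 9.0, 36.0, 3.4, 12
        theta0, delta0 = 95.0, -40.0
        p1 = np.array(
            [[R * math.cos(math.radians(theta0 + i * omega)),
              R * math.sin(math.radians(theta0 + i * omega)), i * h] for i in range(n)]
        )
        p2 = np.array(
            [[R * math.cos(math.radians(delta0 - k * omega)),
              R * math.sin(math.radians(delta0 - k * omega)), (n - 1 - k) * h]
             for k in range(n)]
        )
        gw = hx.groove_widths(p1, p2, radius_correction=5.8)

        def chord(off):
            dang = delta0 - theta0 - (n - 1 + off) * omega
            return math.sqrt(
                (2 * R * math.sin(math.radians(dang) / 2)) ** 2 + (off * h) ** 2
            ) - 5.8

        got = gw.dropna()
        assert np.allclose(got["minor"], chord(hx.MINOR_GROOVE_OFFSET), atol=1e-9)
        assert np.allclose(got["major"], chord(hx.MAJOR_GROOVE_OFFSET), atol=1e-9)

    def test_b_form_minor_below_major_everywhere(self, b_duplex):
        residues, _ = b_duplex
        chains = {}
        for r in residues:
            chains.setdefault(r["chain"], []).append(r)
        p1 = np.array([r["atoms"]["P"] for r in chains["A"] if "P" in r["atoms"]])
        p2 = np.array([r["atoms"]["P"] for r in chains["B"] if "P" in r["atoms"]])
        gw = hx.groove_widths(p1, p2, interior_only=True)
        assert (gw["minor"] < gw["major"]).all()

    def test_a_form_minor_exceeds_b_form_minor(self, a_duplex, b_duplex):
        widths = {}
        for name, (residues, _) in (("A", a_duplex), ("B", b_duplex)):
            chains = {}
            for r in residues:
                chains.setdefault(r["chain"], []).append(r)
            p1 = np.array([r["atoms"]["P"] for r in chains["A"] if "P" in r["atoms"]])
            p2 = np.array([r["atoms"]["P"] for r in chains["B"] if "P" in r["atoms"]])
            widths[name] = hx.groove_widths(p1, p2, interior_only=True)["minor"].mean()
        assert widths["A"] > widths["B"]

    def test_short_strands_rejected(self):
        with pytest.raises(ValueError, match="four phosphates"):
            hx.groove_widths(np.zeros((3, 3)), np.zeros((8, 3)))


class TestDuplexReport:
    def test_b_form_twist_matches_planted(self, b_duplex):
        residues, truth = b_duplex
        rep = hx.duplex_report(residues, exclude_terminal=2).set_index("parameter")["mean"]
        assert rep["twist"] == pytest.approx(truth["htwist"], abs=0.1)
        assert rep["htwist"] == pytest.approx(truth["htwist"], abs=1e-6)
        assert rep["hrise"] == pytest.approx(truth["hrise"], abs=1e-6)
        assert rep["percent_N"] == 0.0

    def test_a_form_reference_row(self, a_duplex):
        residues, _ = a_duplex
        rep = hx.duplex_report(residues, exclude_terminal=2).set_index("parameter")["mean"]
        assert rep["inclination"] == pytest.approx(20.7, abs=0.05)
        assert rep["x_displacement"] == pytest.approx(-5.3, abs=0.05)
        assert rep["percent_N"] == 100.0

    def test_single_pair_has_empty_step_table(self):
        f = hx.helical_frames(1, 36.0, 3.38)[0]
        atoms1 = {k: f.axes @ np.array(v) + f.origin for k, v in hx.STANDARD_BASES["A"].items()}
        flip = np.diag([1.0, -1.0, -1.0])
        atoms2 = {
            k: f.axes @ (flip @ np.array(v)) + f.origin for k, v in hx.STANDARD_BASES["T"].items()
        }
        residues = [
            {"chain": "A", "resseq": 1, "resname": "DA", "atoms": atoms1},
            {"chain": "B", "resseq": 1, "resname": "DT", "atoms": atoms2},
        ]
        rep = hx.duplex_report(residues, exclude_terminal=0).set_index("parameter")
        assert rep.loc["twist", "n"] == 0
        assert rep.loc["shear", "n"] == 1
        assert rep.loc["shear", "mean"] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_leaves_report_unchanged(self, b_duplex, rng):
        residues, _ = b_duplex
        R = Rotation.random(random_state=21).as_matrix()
        t = rng.normal(size=3) * 20
        moved = [dict(r, atoms={k: R @ v + t for k, v in r["atoms"].items()}) for r in residues]
        r0 = hx.duplex_report(residues, exclude_terminal=2).set_index("parameter")["mean"]
        r1 = hx.duplex_report(moved, exclude_terminal=2).set_index("parameter")["mean"]
        for k in r0.index:
            if np.isfinite(r0[k]):
                assert r1[k] == pytest.approx(r0[k], abs=1e-6), k


class TestSuperposeRmsd:
    def test_zero_for_rigidly_moved_copy(self, rng):
        a = rng.normal(size=(20, 3))
        R = Rotation.random(random_state=2).as_matrix()
        b = a @ R.T + np.array([1.0, -2.0, 0.5])
        assert hx.superpose_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)
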