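import math

import numpy as np
import pytest

from porescope import contacts as C
from porescope.model_io import Frame
from porescope.synthetic_data import make_contact_fixture, run_fixture_detectors

CRIT = C.InteractionCriteria()


def frame_of(coords, box=None):
    return Frame(0.0, np.asarray(coords, dtype=float),
                 None if box is None else np.asarray(box, dtype=float))


class TestElectrostatic:
    def test_inclusive_boundary(self):
        for d, hits in [(3.9, 1), (4.0, 1), (4.1, 0)]:
            f = frame_of([[0, 0, 0], [d, 0, 0]])
            recs = C.detect_electrostatic(f, {"lig": [0]}, {"res": [1]}, CRIT)
            assert len(recs) == hits, d

    def test_min_distance_stored(self):
        f = frame_of([[0, 0, 0], [3.0, 0, 0], [2.0, 0, 0]])
        recs = C.detect_electrostatic(f, {"lig": [0]}, {"res": [1, 2]}, CRIT)
        assert len(recs) == 1
        assert recs[0].distance_A == pytest.approx(2.0)

    def test_empty_selection_errors(self):
        f = frame_of([[0, 0, 0]])
        with pytest.raises(ValueError):
            C.detect_electrostatic(f, {}, {"res": [0]}, CRIT)
        with pytest.raises(ValueError):
            C.detect_electrostatic(f, {"lig": [0]}, {"res": []}, CRIT)

    def test_minimum_image(self):
        # 19 A apart in a 20 A box -> 1 A through the boundary
        f = frame_of([[0.5, 0, 0], [19.5, 0, 0]], box=[20, 20, 20])
        recs = C.detect_electrostatic(f, {"lig": [0]}, {"res": [1]}, CRIT)
        assert len(recs) == 1
        assert recs[0].distance_A == pytest.approx(1.0)

    def test_brute_force_oracle_random_frames(self, rng):
        for _ in range(25):
            coords = rng.uniform(0, 12, (12, 3))
            f = frame_of(coords)
            ogroups = {"l1": [0, 1, 2], "l2": [3, 4]}
            ngroups = {"r1": [5, 6], "r2": [7], "r3": [8, 9, 10]}
            recs = C.detect_electrostatic(f, ogroups, ngroups, CRIT)
            found = {(r.partner_a, r.partner_b) for r in recs}
            expected = set()
            for lig, oidx in ogroups.items():
                for res, nidx in ngroups.items():
                    dmin = min(
                        math.dist(coords[o], coords[n]) for o in oidx for n in nidx
                    )
                    if dmin <= 4.0:
                        expected.add((lig, res))
            assert found == expected


class TestCationPairing:
    def test_strict_boundary(self):
        for d, hits in [(3.5, 1), (4.0, 0)]:
            f = frame_of([[0, 0, 0], [d, 0, 0]])
            recs = C.detect_cation_pairing(f, {"p": [0]}, {"na": 1}, CRIT)
            assert len(recs) == hits, d

    def test_random_frame_oracle(self, rng):
        coords = rng.uniform(0, 10, (8, 3))
        f = frame_of(coords)
        recs = C.detect_cation_pairing(f, {"p": [0, 1, 2]}, [3, 4, 5, 6, 7], CRIT)
        found = {r.partner_b for r in recs}
        expected = {
            f"cation{j}"
            for j, c in enumerate(range(3, 8))
            if min(math.dist(coords[o], coords[c]) for o in range(3)) < 4.0
        }
        assert found == expected


class TestRingPlane:
    def test_equilateral_in_xy(self):
        f = frame_of([[1, 0, 0], [-0.5, 0.866, 0], [-0.5, -0.866, 0]])
        center, normal = C.ring_plane(f, (0, 1, 2))
        np.testing.assert_allclose(np.abs(normal), [0, 0, 1], atol=1e-9)

    def test_equal_masses_centroid(self):
        f = frame_of([[0, 0, 0], [3, 0, 0], [0, 3, 0]])
        center, _ = C.ring_plane(f, (0, 1, 2))
        np.testing.assert_allclose(center, [1, 1, 0])

    def test_mass_weighted_center(self):
        f = frame_of([[0, 0, 0], [3, 0, 0], [0, 3, 0]])
        center, _ = C.ring_plane(f, (0, 1, 2), masses=[2, 1, 1])
        np.testing.assert_allclose(center, [0.75, 0.75, 0])

    def test_normal_orthogonal_to_edges(self, rng):
        coords = rng.uniform(-5, 5, (3, 3))
        f = frame_of(coords)
        _, normal = C.ring_plane(f, (0, 1, 2))
        assert abs(np.dot(normal, coords[1] - coords[0])) < 1e-10
        assert abs(np.dot(normal, coords[2] - coords[0])) < 1e-10

    def test_collinear_errors(self):
        f = frame_of([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            C.ring_plane(f, (0, 1, 2))


class TestFixtures:
    @pytest.mark.parametrize(
        "kind",
        ["electrostatic", "pairing", "pipi", "cationpi", "guanidinium", "hbond"],
    )
    def test_fixture_expectations(self, kind):
        fx = make_contact_fixture(kind)
        assert run_fixture_detectors(fx) == fx.expected

    def test_boundary_cases_covers_all(self):
        fixtures = make_contact_fixture("boundary_cases")
        assert {f.kind for f in fixtures} == {
            "electrostatic", "pairing", "pipi", "cationpi", "guanidinium", "hbond"
        }
        for fx in fixtures:
            assert run_fixture_detectors(fx) == fx.expected


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("kind", ["electrostatic", "pairing", "pipi",
                                      "cationpi", "guanidinium", "hbond"])
    def test_rotation_translation(self, kind, rng):
        fx = make_contact_fixture(kind)
        baseline = run_fixture_detectors(fx)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.uniform(-30, 30, 3)
        fx.frame.coords = fx.frame.coords @ q.T + shift
        assert run_fixture_detectors(fx) == baseline


class TestHbond:
    def test_misspecified_donor_errors(self):
        f = frame_of([[0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="1.2"):
            C.detect_hbond(f, [(0, 1)], [2], CRIT)

    def test_angles_folded_in_range(self, rng):
        for _ in range(50):
            u, v = rng.normal(size=3), rng.normal(size=3)
            a = C._folded_angle_deg(u, v)
            assert 0.0 <= a <= 90.0


class TestTimelines:
    def test_long_run(self):
        recs = [C.ContactRecord(k, "electrostatic", "l", "r", 3.0) for k in range(100)]
        tl = C.build_timelines(recs)
        stats = C.classify_longlived(tl, 0.1, CRIT)
        s = stats[("l", "r", "electrostatic")]
        assert s.max_run_ns == pytest.approx(10.0)
        assert s.is_longlived

    def test_scattered_not_longlived(self):
        recs = [C.ContactRecord(k, "hbond", "l", "r", 3.0) for k in (0, 2, 4)]
        stats = C.classify_longlived(C.build_timelines(recs), 0.1, CRIT)
        s = stats[("l", "r", "hbond")]
        assert s.max_run_ns == pytest.approx(0.1)
        assert s.n_runs == 3
        assert not s.is_longlived

    def test_threshold_is_strict(self):
        # exactly 5.0 ns (50 frames at 0.1 ns) is NOT long-lived (> 5 ns strict)
        recs = [C.ContactRecord(k, "hbond", "l", "r", 3.0) for k in range(50)]
        stats = C.classify_longlived(C.build_timelines(recs), 0.1, CRIT)
        assert stats[("l", "r", "hbond")].max_run_ns == pytest.approx(5.0)
        assert not stats[("l", "r", "hbond")].is_longlived

    def test_alternating_pattern_matches_rle_oracle(self, rng):
        present = rng.uniform(size=200) < 0.5
        recs = [C.ContactRecord(k, "hbond", "l", "r", 3.0)
                for k in range(200) if present[k]]
        stats = C.classify_longlived(C.build_timelines(recs), 0.25, CRIT)
        # independent run-length encoding
        best, run = 0, 0
        for p in present:
            run = run + 1 if p else 0
            best = max(best, run)
        if best == 0:
            assert ("l", "r", "hbond") not in stats
        else:
            assert stats[("l", "r", "hbond")].max_run_ns == pytest.approx(best * 0.25)
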