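"""Digitization reading, Kabsch alignment, templating and correction."""

from __future__ import annotations

import numpy as np
import pytest

from dotkit import digitization as dig
from dotkit.synthetic import make_cap_layout

from conftest import random_rigid_transform


def _layout_cap(cap_id="c1"):
    cap = make_cap_layout(48.0, n_sources=8, n_detectors=8)
    cap = cap.copy()
    cap.cap_id = cap_id
    return cap


def _template_from(cap):
    return dig.Template(cap_size_cm=cap.cap_size_cm, points=cap.points.copy(),
                        roles=list(cap.roles), labels=list(cap.labels),
                        n_contributing=1, threshold_cm=0.0)


class TestReadWrite:
    def test_roles_assigned_by_position(self, tmp_path):
        p = tmp_path / "dig.txt"
        p.write_text("0 0 0\n1 0 0\n0 1 0\n")
        cap = dig.read_polhemus(p, dig.LayoutSpec(1, 1, 1))
        assert cap.roles == ["landmark", "source", "detector"]
        np.testing.assert_allclose(cap.points,
                                   [[0, 0, 0], [1, 0, 0], [0, 1, 0]])

    def test_empty_file_is_parse_error(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        with pytest.raises(dig.DigitizationParseError):
            dig.read_polhemus(p, dig.LayoutSpec(1, 1, 1))

    def test_non_numeric_row_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0 0\nx y z\n0 1 0\n")
        with pytest.raises(dig.DigitizationParseError):
            dig.read_polhemus(p, dig.LayoutSpec(1, 1, 1))

    def test_row_count_mismatch(self, tmp_path):
        p = tmp_path / "short.txt"
        p.write_text("0 0 0\n1 0 0\n")
        with pytest.raises(dig.LayoutMismatchError):
            dig.read_polhemus(p, dig.LayoutSpec(1, 1, 1))

    def test_inches_converted_to_cm(self, tmp_path):
        p = tmp_path / "inches.txt"
        p.write_text("1 0 0\n0 1 0\n0 0 1\n")
        cap = dig.read_polhemus(p, dig.LayoutSpec(1, 1, 1, unit="in"))
        np.testing.assert_allclose(cap.points.max(), 2.54)

    def test_polhemus_round_trip(self, tmp_path, rng):
        cap = _layout_cap()
        cap.points += rng.normal(size=cap.points.shape)
        path = dig.write_polhemus(cap, tmp_path / "rt.txt")
        back = dig.read_polhemus(
            path, dig.LayoutSpec(5, 8, 8), cap_size_cm=48.0)
        np.testing.assert_allclose(back.points, cap.points, atol=1e-6)

    def test_digpts_export_format_and_mm(self, tmp_path):
        cap = dig.Cap("sub01", 48.0, [[1.0, 2.0, 3.0]], ["source"], ["s1"])
        out = dig.save_digpts(cap, tmp_path)
        assert out.parent.name == "sub01"
        line = out.read_text().strip()
        label, coords = line.split(":")
        assert label == "s1"
        np.testing.assert_allclose([float(v) for v in coords.split()],
                                   [10.0, 20.0, 30.0])

    def test_digpts_without_detectors(self, tmp_path):
        cap = dig.Cap("sub02", 48.0, [[0, 0, 0], [1, 1, 1]],
                      ["landmark", "source"], ["nz", "s1"])
        out = dig.save_digpts(cap, tmp_path)
        assert len(out.read_text().strip().splitlines()) == 2

    def test_digpts_round_trip(self, tmp_path, rng):
        cap = _layout_cap("sub03")
        cap.points += rng.normal(size=cap.points.shape)
        out = dig.save_digpts(cap, tmp_path)
        back = dig.read_digpts(out, cap_size_cm=48.0)
        np.testing.assert_allclose(back.points, cap.points, atol=1e-7)
        assert back.labels == cap.labels
        assert back.roles == cap.roles


class TestKabsch:
    def test_self_alignment_is_identity(self):
        cap = _layout_cap()
        tf, aligned, dists = dig.kabsch_align(cap, cap)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation, 0, atol=1e-12)
        assert dists.max() < 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_recovers_random_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        ref = _layout_cap()
        rot, trans = random_rigid_transform(rng)
        moved = ref.copy()
        moved.points = ref.points @ rot.T + trans
        tf, aligned, dists = dig.kabsch_align(moved, ref)
        assert dig.rmsd(aligned.points, ref.points) < 1e-8
        np.testing.assert_allclose(tf.rotation, rot.T, atol=1e-8)

    def test_known_rotation_and_shift(self):
        ref = _layout_cap()
        th = np.deg2rad(30)
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        moved = ref.copy()
        moved.points = ref.points @ rot.T + np.array([5.0, 0, 0])
        _, aligned, _ = dig.kabsch_align(moved, ref)
        assert dig.rmsd(aligned.points, ref.points) < 1e-8

    def test_mirror_still_proper_rotation(self):
        ref = _layout_cap()
        mirrored = ref.copy()
        mirrored.points = ref.points * np.array([-1.0, 1.0, 1.0])
        tf, aligned, _ = dig.kabsch_align(mirrored, ref)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0)
        # a reflection cannot be undone by a proper rotation
        assert dig.rmsd(aligned.points, ref.points) > 0.1

    def test_alignment_never_increases_rmsd(self, rng):
        ref = _layout_cap()
        for _ in range(5):
            noisy = ref.copy()
            rot, trans = random_rigid_transform(rng)
            noisy.points = (ref.points + rng.normal(
                scale=1.0, size=ref.points.shape)) @ rot.T + trans
            before = dig.rmsd(noisy.points, ref.points)
            _, aligned, _ = dig.kabsch_align(noisy, ref)
            assert dig.rmsd(aligned.points, ref.points) <= before + 1e-12

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]])
        cap = dig.Cap("line", 0, pts, ["landmark"] * 4, list("abcd"))
        with pytest.raises(dig.UnderdeterminedAlignmentError):
            dig.kabsch_align(cap, cap, point_subset=[0, 1, 2])


class TestBuildTemplate:
    def test_identical_caps_give_that_cap(self):
        caps = [_layout_cap(f"c{i}") for i in range(3)]
        tpl = dig.build_template(caps, threshold_cm=10.0)
        np.testing.assert_allclose(tpl.points, caps[0].points, atol=1e-8)
        assert tpl.n_contributing == 3

    def test_outlier_cap_excluded_from_mean(self):
        a = _layout_cap("a")
        b = _layout_cap("b")
        c = _layout_cap("c")
        c.points = c.points.copy()
        c.points[0] += np.array([15.0, 0, 0])
        tpl = dig.build_template([a, b, c], threshold_cm=10.0)
        # c's displaced point exceeds 10 cm, so template = mean(a, b) = a
        np.testing.assert_allclose(tpl.points, a.points, atol=1e-8)
        assert tpl.n_contributing == 2

    def test_order_invariant(self, rng):
        base = _layout_cap("x")
        caps = []
        for i in range(4):
            c = base.copy()
            c.cap_id = f"c{i}"
            c.points = base.points + rng.normal(scale=0.2,
                                                size=base.points.shape)
            caps.append(c)
        t1 = dig.build_template(caps, 10.0)
        t2 = dig.build_template(caps[::-1], 10.0)
        np.testing.assert_allclose(t1.points, t2.points, atol=1e-8)
        assert t1.reference_id == t2.reference_id

    def test_no_consensus_raises_with_distances(self):
        a = _layout_cap("a")
        b = _layout_cap("b")
        b.points = b.points + 0.0
        b.points[0] += 50.0  # each cap fails to match the other
        with pytest.raises(dig.NoConsensusError) as exc:
            dig.build_template([a, b], threshold_cm=1e-6)
        assert exc.value.pairwise_distances.shape == (2, 2)


class TestThreeStep:
    def test_displaced_nasion_selftest(self):
        """Template caps with a far-displaced NZ: only that point corrected."""
        base = _layout_cap("tpl")
        tpl = _template_from(base)
        for direction in ([0, 20.0, 10.0], [-15.0, 5.0, 0]):
            cap = base.copy()
            cap.points = cap.points.copy()
            cap.points[0] += np.asarray(direction)  # NZ is stored first
            corrected, report = dig.threestep_alignment(cap, tpl, 12, 10, 7)
            assert list(report.replaced_indices) == [0]
            np.testing.assert_allclose(corrected.points, base.points,
                                       atol=1e-8)
            assert corrected.replaced_mask[0]
            assert not corrected.replaced_mask[1:].any()

    def test_cap_equal_to_template_untouched(self):
        base = _layout_cap()
        corrected, report = dig.threestep_alignment(base, _template_from(base),
                                                    12, 10, 7)
        assert report.replaced_indices.size == 0
        assert report.proportion_replaced == 0.0

    def test_mid_distance_points_caught_by_later_passes(self):
        """9 cm fails only the 7 cm pass; 13 cm fails the first (12 cm)."""
        base = _layout_cap()
        cap = base.copy()
        cap.points = cap.points.copy()
        cap.points[6] += np.array([0, 0, 9.0])
        cap.points[12] += np.array([0, 13.0, 0])
        corrected, report = dig.threestep_alignment(cap, _template_from(base),
                                                    12, 10, 7)
        assert sorted(report.replaced_indices) == [6, 12]
        np.testing.assert_allclose(corrected.points, base.points, atol=1e-6)

    def test_correction_is_conservative(self, rng):
        """Non-replaced points equal the plain aligned input points."""
        base = _layout_cap()
        tpl = _template_from(base)
        cap = base.copy()
        cap.points = base.points + rng.normal(scale=0.3,
                                              size=base.points.shape)
        cap.points[3] += 30.0
        corrected, report = dig.threestep_alignment(cap, tpl, 12, 10, 7)
        kept = np.ones(cap.n_points, bool)
        kept[report.replaced_indices] = False
        _, aligned, _ = dig.kabsch_align(cap, tpl, np.flatnonzero(kept))
        np.testing.assert_allclose(corrected.points[kept],
                                   aligned.points[kept], atol=1e-10)

    def test_bad_threshold_order_rejected(self):
        base = _layout_cap()
        with pytest.raises(ValueError):
            dig.threestep_alignment(base, _template_from(base), 7, 10, 12)


class TestIterative:
    def test_already_settled_cap_untouched(self):
        base = _layout_cap()
        corrected, report = dig.iterative_alignment(base,
                                                    _template_from(base), 0.5)
        assert report.replaced_indices.size == 0

    def test_moderate_outlier_replaced_when_threshold_reaches_it(self):
        base = _layout_cap()
        cap = base.copy()
        cap.points = cap.points.copy()
        cap.points[8] += np.array([0, 0, 4.2])
        tpl = _template_from(base)
        corrected, report = dig.iterative_alignment(cap, tpl,
                                                    max_prop_replaced=0.5)
        assert list(report.replaced_indices) == [8]
        # independent pass-by-pass trace: decrement from 20 cm by 1 cm,
        # dropping and re-aligning, until the outlier is caught
        retained = np.ones(cap.n_points, bool)
        expected_drop_at = None
        for thr in np.arange(20.0, 0.0, -1.0):
            _, _, dists = dig.kabsch_align(cap, tpl,
                                           np.flatnonzero(retained))
            if np.all(dists[retained] <= 0.5):
                break
            hit = retained & (dists > thr)
            if hit.any():
                expected_drop_at = thr
                retained &= ~hit
        assert expected_drop_at is not None
        # the outlier sits ~4.2 cm out, so it is caught near that threshold
        assert 3.0 <= expected_drop_at <= 5.0
        assert report.thresholds_cm[-1] == pytest.approx(expected_drop_at)

    def test_threshold_decrements_by_one_cm(self):
        base = _layout_cap()
        cap = base.copy()
        cap.points = cap.points + np.random.default_rng(0).normal(
            scale=0.8, size=cap.points.shape)
        _, report = dig.iterative_alignment(cap, _template_from(base), 0.5)
        assert report.thresholds_cm[0] == pytest.approx(20.0)
        if len(report.thresholds_cm) > 1:
            assert report.thresholds_cm[1] == pytest.approx(19.0)

    def test_stops_before_exceeding_replacement_budget(self):
        base = _layout_cap()
        cap = base.copy()
        cap.points = cap.points.copy()
        cap.points[5:9] += 30.0  # 4 of 21 points far out
        _, report = dig.iterative_alignment(cap, _template_from(base),
                                            max_prop_replaced=2 / 21)
        assert report.proportion_replaced <= 2 / 21


class TestHeadwise:
    def test_template_cap_kept(self):
        base = _layout_cap()
        (cap, replaced), = dig.headwise_alignment([base],
                                                  _template_from(base), 5.0)
        assert not replaced
        np.testing.assert_allclose(cap.points, base.points, atol=1e-8)

    def test_distorted_cap_replaced(self, rng):
        base = _layout_cap()
        cap = base.copy()
        # non-rigid distortion with a known large mean residual
        offs = rng.normal(size=base.points.shape)
        offs = offs / np.linalg.norm(offs, axis=1, keepdims=True) * 8.0
        cap.points = base.points + offs
        (out, replaced), = dig.headwise_alignment([cap], _template_from(base),
                                                  threshold_cm=5.0)
        assert replaced
        np.testing.assert_allclose(out.points, base.points)
        assert out.replaced_mask.all()

    def test_infinite_threshold_keeps_everything(self, rng):
        base = _layout_cap()
        caps = []
        for i in range(3):
            c = base.copy()
            c.cap_id = f"c{i}"
            c.points = base.points + rng.normal(scale=2.0,
                                                size=base.points.shape)
            caps.append(c)
        results = dig.headwise_alignment(caps, _template_from(base), np.inf)
        assert all(not replaced for _, replaced in results)
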