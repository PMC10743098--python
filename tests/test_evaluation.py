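"""Local/regional/global metrics, ROI volume change, PRM, and agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lungjac.deformation import JacobianMap
from lungjac.evaluation import (
    JMU_EXCLUSION_BAND, agreement_summary, dice_quartile, global_stats,
    local_metrics, prm_classify, roi_volume_change,
)
from lungjac.volumes import LungMask, ROILabelMap, Volume3D


def _jmap(data, spacing=3.0):
    return JacobianMap.from_J(
        Volume3D(np.asarray(data, dtype=np.float32), spacing=(spacing,) * 3,
                 intensity_kind="jacobian"))


def _mask(shape):
    return LungMask(np.ones(shape, dtype=np.uint8), spacing=(3.0,) * 3)


class TestLocalMetrics:
    def test_identity_control(self, rng):
        j = _jmap(np.exp2(rng.standard_normal((8, 8, 8)) * 0.3))
        m = _mask((8, 8, 8))
        out = local_metrics(j, j, m)
        assert out.mae == 0.0
        assert out.spearman == pytest.approx(1.0)
        assert out.ssim == pytest.approx(1.0)
        assert out.psnr == 300.0  # capped at the zero-error ceiling
        assert out.dice_low == 1.0 and out.dice_high == 1.0

    def test_spearman_matches_rank_formula_oracle(self, rng):
        vals_a = np.array([1.1, 0.8, 1.5, 2.0, 0.9, 1.3, 1.7, 0.7, 1.05, 1.9])
        vals_b = np.array([1.2, 0.85, 1.4, 1.8, 1.1, 1.25, 1.75, 0.75, 1.0, 2.1])
        a = _jmap(vals_a.reshape(1, 2, 5))
        b = _jmap(vals_b.reshape(1, 2, 5))
        out = local_metrics(a, b, _mask((1, 2, 5)))
        # brute-force rank computation
        ra = stats.rankdata(np.abs(np.log2(vals_a)))
        rb = stats.rankdata(np.abs(np.log2(vals_b)))
        rho = np.corrcoef(ra, rb)[0, 1]
        assert out.spearman == pytest.approx(rho, abs=1e-12)

    def test_permutation_null_gives_small_correlation(self, rng):
        vals = np.exp2(rng.standard_normal(1000) * 0.4)
        perm = rng.permutation(vals)
        a = _jmap(vals.reshape(10, 10, 10))
        b = _jmap(perm.reshape(10, 10, 10))
        out = local_metrics(a, b, _mask((10, 10, 10)))
        assert abs(out.spearman) < 0.2

    def test_constant_input_flagged(self):
        a = _jmap(np.full((4, 4, 4), 2.0))
        out = local_metrics(a, a, _mask((4, 4, 4)))
        assert not out.spearman_defined
        assert np.isnan(out.spearman)


class TestDiceQuartile:
    def test_hand_counted_example(self):
        # 8 voxels; lower quartile = 2 smallest values of each map
        ref = np.array([1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7]).reshape(2, 2, 2)
        pred = np.array([1.0, 1.1, 1.6, 1.3, 1.4, 1.5, 1.2, 1.7]).reshape(2, 2, 2)
        m = _mask((2, 2, 2))
        # low quartile: ref {1.0, 1.1}, pred {1.0, 1.1} -> Dice 1
        assert dice_quartile(_jmap(ref), _jmap(pred), m, "low") == pytest.approx(1.0)
        # high quartile: ref {1.6, 1.7}, pred {1.6(idx2), 1.7} -> overlap {1.7} -> 2*1/4
        assert dice_quartile(_jmap(ref), _jmap(pred), m, "high") == pytest.approx(0.5)

    def test_reversed_gradient_has_no_overlap(self):
        grad = np.linspace(1.0, 2.0, 64).reshape(4, 4, 4)
        rev = grad[::-1, ::-1, ::-1].copy()
        m = _mask((4, 4, 4))
        assert dice_quartile(_jmap(grad), _jmap(rev), m, "low") == 0.0
        assert dice_quartile(_jmap(grad), _jmap(rev), m, "high") == 0.0

    def test_regions_are_quarter_sized(self, rng):
        j = _jmap(np.exp2(rng.standard_normal((8, 8, 8)) * 0.3))
        m = _mask((8, 8, 8))
        jd = np.asarray(j.J.data)
        thr = np.percentile(jd, 25)
        assert (jd < thr).sum() == pytest.approx(0.25 * jd.size, abs=1)


class TestGlobalStats:
    def test_constant_field(self):
        g = global_stats(_jmap(np.full((4, 4, 4), 2.0)), _mask((4, 4, 4)))
        assert g.j_mean == pytest.approx(2.0)
        assert g.j_cv == pytest.approx(0.0)

    def test_two_voxel_hand_arithmetic(self):
        data = np.array([1.0, 3.0]).reshape(1, 1, 2)
        g = global_stats(_jmap(data), _mask((1, 1, 2)))
        assert g.j_mean == pytest.approx(2.0)
        assert g.j_cv == pytest.approx(0.5)  # population sd 1.0 over mean 2.0

    def test_affine_phantom_effort(self, affine_case):
        g = global_stats(affine_case.J_FRC, affine_case.M_FRC)
        assert g.j_mean == pytest.approx(2.0, abs=1e-6)


class TestROIVolumeChange:
    def _two_rois(self, j_left, j_right):
        j = np.empty((2, 2, 2), dtype=np.float32)
        j[0] = j_left
        j[1] = j_right
        labels = np.empty((2, 2, 2), dtype=np.uint16)
        labels[0], labels[1] = 1, 2
        rois = ROILabelMap(labels, {1: "L", 2: "R"}, spacing=(3.0,) * 3)
        return _jmap(j), rois, _mask((2, 2, 2))

    def test_hand_arithmetic_equal_volume_rois(self):
        jmap, rois, m = self._two_rois(1.5, 2.5)
        out = roi_volume_change(jmap, rois, m)
        pct = dict(zip(out.table["name"], out.table["dv_pct"]))
        assert pct["L"] == pytest.approx(25.0)
        assert pct["R"] == pytest.approx(75.0)

    def test_zero_change_roi(self):
        jmap, rois, m = self._two_rois(1.0, 2.0)
        out = roi_volume_change(jmap, rois, m)
        assert out.table.set_index("name").loc["L", "dv_mm3"] == pytest.approx(0.0)

    def test_partition_conservation(self, rng):
        j = np.exp2(rng.standard_normal((4, 4, 4)) * 0.4).astype(np.float32)
        labels = rng.integers(1, 4, size=(4, 4, 4)).astype(np.uint16)
        rois = ROILabelMap(labels, {1: "a", 2: "b", 3: "c"}, spacing=(3.0,) * 3)
        out = roi_volume_change(_jmap(j), rois, _mask((4, 4, 4)))
        assert out.table["dv_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_near_unity_case_excluded(self):
        jmap, rois, m = self._two_rois(1.012, 1.008)  # J_mu = 1.01
        out = roi_volume_change(jmap, rois, m)
        assert out.excluded
        assert abs(out.j_mean_lung - 1.0) < JMU_EXCLUSION_BAND

    def test_non_partition_rejected(self):
        jmap, rois, m = self._two_rois(1.5, 2.5)
        bad = np.asarray(rois.data).copy()
        bad[0, 0, 0] = 0
        with pytest.raises(ValueError, match="partition"):
            roi_volume_change(jmap, ROILabelMap(bad, rois.label_table, rois.spacing), m)


class TestPRM:
    @pytest.mark.parametrize("frc,tlc,expected", [
        (-900.0, -960.0, "emphysema"),
        (-900.0, -940.0, "fsad"),
        (-800.0, -940.0, "normal"),
        (-800.0, -960.0, "normal"),   # FRC >= -856 dominates
    ])
    def test_threshold_rules(self, frc, tlc, expected):
        shape = (2, 2, 2)
        vf = Volume3D(np.full(shape, frc, dtype=np.float32))
        vt = Volume3D(np.full(shape, tlc, dtype=np.float32))
        lab = prm_classify(vf, vt, _mask(shape))
        names = {v: k for k, v in lab.label_table.items()}
        assert np.all(np.asarray(lab.data) == names[expected])

    def test_classes_partition_mask(self, rng):
        shape = (6, 6, 6)
        vf = Volume3D(rng.uniform(-1000, -700, shape).astype(np.float32))
        vt = Volume3D(rng.uniform(-1000, -800, shape).astype(np.float32))
        m = LungMask((rng.random(shape) > 0.4).astype(np.uint8), spacing=(3.0,) * 3)
        lab = prm_classify(vf, vt, m)
        lab.check_partition(m)


class TestAgreement:
    def test_identity_pairs(self):
        pairs = [(1.0, 1.0), (1.5, 1.5), (2.0, 2.0), (2.5, 2.5)]
        s = agreement_summary(pairs)
        assert s.slope == pytest.approx(1.0)
        assert s.intercept == pytest.approx(0.0, abs=1e-12)
        assert s.r2 == pytest.approx(1.0)
        assert s.ba_mean == 0.0 and s.ba_lo == 0.0 and s.ba_hi == 0.0

    def test_normal_equations_oracle(self):
        pairs = np.array([(1.2, 1.0), (1.9, 1.5), (2.6, 2.0), (2.8, 2.5)])
        s = agreement_summary(pairs)
        x, y = pairs[:, 1], pairs[:, 0]
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert s.slope == pytest.approx(slope, abs=1e-12)
        assert s.intercept == pytest.approx(intercept, abs=1e-12)
        assert s.r2 == pytest.approx(r2, abs=1e-12)

    def test_constant_shift(self):
        ref = np.array([1.0, 1.5, 2.0, 2.7])
        s = agreement_summary(list(zip(ref + 0.3, ref)))
        assert s.slope == pytest.approx(1.0)
        assert s.ba_mean == pytest.approx(0.3)

    def test_zero_reference_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            agreement_summary([(1.0, 2.0), (1.5, 2.0), (2.0, 2.0)])

    def test_groups(self):
        pairs = [(1.1, 1.0), (1.6, 1.5), (2.2, 2.0), (2.4, 2.5)]
        s = agreement_summary(pairs, groups=["a", "a", "b", "b"])
        assert set(s.by_group["group"]) == {"a", "b"}
        row = s.by_group.set_index("group").loc["a"]
        assert row["ba_mean"] == pytest.approx(0.1)
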