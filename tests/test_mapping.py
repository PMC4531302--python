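"""Subject-level network reconstruction and ROI placement."""
import numpy as np
import pytest
from scipy import stats

from roifc.core import BoldRun, GridError, NodeSpec, RoiCube, StatMap
from roifc.mapping import (glm_zmap, literature_roi_set, roi_in_network,
                           roi_mean_zstat, subject_network_timecourse,
                           subject_roi_set)
from roifc.synthetic import (CohortConfig, battery_nodes, generate_cohort)
from conftest import GRID, VOXEL, two_network_templates

AFF = np.diag([2.0, 2.0, 2.0, 1.0])


class TestSubjectTimecourse:
    def test_segment_bookkeeping(self, small_analysis):
        cs = small_analysis["cs"]
        seg = cs.segment("sub-02")
        raw = cs.mixing[seg.start:seg.start + seg.length, 3]
        tc = subject_network_timecourse(cs, 3, "sub-02")
        # same series up to demeaning and scaling
        assert abs(np.corrcoef(raw, tc)[0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_unit_variance_contract(self, small_analysis):
        tc = subject_network_timecourse(small_analysis["cs"], 0, "sub-01")
        assert tc.std() == pytest.approx(1.0, abs=1e-12)
        assert tc.mean() == pytest.approx(0.0, abs=1e-12)

    def test_segments_round_trip_mixing_column(self, small_analysis):
        cs = small_analysis["cs"]
        col = np.concatenate(
            [cs.mixing[s.start:s.start + s.length, 1] for s in cs.segments])
        assert np.array_equal(col, cs.mixing[:, 1])

    def test_unknown_subject_rejected(self, small_analysis):
        with pytest.raises(KeyError, match="nobody"):
            subject_network_timecourse(small_analysis["cs"], 0, "nobody")


class TestGlmZmap:
    def _run(self, data):
        return BoldRun(data=data, affine=AFF, tr_s=2.0, subject_id="s")

    def test_perfect_fit_hits_the_cap(self, rng):
        reg = rng.standard_normal(30)
        data = np.zeros((3, 3, 3, 30))
        data[1, 1, 1] = 2.5 * reg + 1.0
        zm = glm_zmap(self._run(data), reg, z_cap=38.0)
        assert zm.values[1, 1, 1] == 38.0

    def test_null_voxels_give_standard_normal_z(self):
        rng = np.random.default_rng(99)
        data = rng.standard_normal((25, 20, 20, 120))
        reg = rng.standard_normal(120)
        zm = glm_zmap(self._run(data), reg)
        z = zm.values.ravel()
        assert abs(z.mean()) < 0.05
        assert 0.9 < z.var() < 1.1

    def test_z_monotone_in_correlation_via_t_identity(self, rng):
        """z must be the t->normal quantile map of t = r sqrt((T-2)/(1-r^2))."""
        n_t = 50
        reg = rng.standard_normal(n_t)
        data = np.zeros((5, 1, 1, n_t))
        noise = rng.standard_normal(n_t)  # shared, so r grows with the mix
        for i, mix in enumerate([0.0, 0.3, 0.8, 2.0, 5.0]):
            data[i, 0, 0] = mix * reg + noise
        zm = glm_zmap(self._run(data), reg)
        zs = zm.values[:, 0, 0]
        regc = (reg - reg.mean()) / reg.std()
        for i in range(5):
            v = data[i, 0, 0]
            r = np.corrcoef(v, regc)[0, 1]
            t = r * np.sqrt((n_t - 2) / (1 - r ** 2))
            expect = np.sign(t) * stats.norm.isf(stats.t.sf(abs(t), n_t - 2))
            assert zs[i] == pytest.approx(expect, abs=1e-9)
        assert np.all(np.diff(zs) > 0)

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            glm_zmap(self._run(np.zeros((2, 2, 2, 10))), np.ones(10))

    def test_zero_variance_voxel_maps_to_zero(self, rng):
        reg = rng.standard_normal(20)
        data = np.zeros((2, 2, 2, 20))
        zm = glm_zmap(self._run(data), reg)
        assert np.all(zm.values == 0.0)


class TestSubjectRoiSet:
    def test_recovers_jittered_node_against_true_regressor(self):
        """A node displaced +4 mm is found at its displaced position, not the
        canonical one, when the subject's map is reconstructed from the
        (noise-free in the limit) planted signal."""
        tpl = two_network_templates()
        cfg = CohortConfig(n_subjects=1, grid_shape=GRID, jitter_sd_mm=0.0,
                           noise_sd=0.4, n_timepoints=80, seed=12,
                           coupling={})
        runs, truth = generate_cohort(tpl, cfg)
        run = runs[0]
        # displace node A.n1 manually: regenerate with planted offset
        shifted = [t for t in tpl]
        centers = list(shifted[0].node_centers)
        centers[0] = (centers[0][0] + 4.0, centers[0][1], centers[0][2])
        from roifc.synthetic import NetworkTemplate
        shifted[0] = NetworkTemplate("A", tuple(centers),
                                     blob_fwhm_mm=8.0, within_corr=0.8)
        runs, truth = generate_cohort(shifted, cfg)
        run = runs[0]
        nodes = battery_nodes(tpl, search_radius_mm=14.0)  # canonical battery
        mask = np.ones(GRID, dtype=bool)
        zmaps = {net: glm_zmap(run, truth.signals["sub-01"][:, 0 if net == "A"
                                                            else 3],
                               mask, network_id=net)
                 for net in ("A", "B")}
        ss = subject_roi_set(zmaps, nodes, mask)
        placed = ss.roi("A.n1").center_voxel * VOXEL
        planted = np.asarray(truth.centers["sub-01"]["A.n1"])
        canonical = np.asarray(tpl[0].node_centers[0])
        assert np.linalg.norm(placed - planted) <= 2.0 + 1e-9
        assert np.linalg.norm(placed - canonical) >= 2.0

    def test_true_regressor_recovery_median_within_one_voxel(self):
        """With the node's own signal as regressor at SNR 2 and 6 mm jitter,
        the median placement error across a cohort stays within one voxel."""
        tpl = two_network_templates()
        cfg = CohortConfig(n_subjects=10, grid_shape=GRID, jitter_sd_mm=6.0,
                           noise_sd=0.5, n_timepoints=100, seed=7,
                           coupling={})
        runs, truth = generate_cohort(tpl, cfg)
        nodes = battery_nodes(tpl, search_radius_mm=20.0)
        mask = np.ones(GRID, dtype=bool)
        errs = []
        for run in runs:
            sig = truth.signals[run.subject_id]
            for col, node in enumerate(nodes):
                zm = glm_zmap(run, sig[:, col], mask,
                              network_id=node.network_id)
                from roifc.ica import peak_coordinate
                pc = peak_coordinate(zm.values, node, mask, run.affine)
                planted = np.asarray(truth.centers[run.subject_id][node.label])
                errs.append(np.linalg.norm(pc * VOXEL - planted))
        assert np.median(errs) <= 2.0 + 1e-9

    def test_zero_jitter_cohort_agrees_with_group_rois(self, small_mask):
        """Without spatial variability the subject-specific centres coincide
        with the group-ROI centres (median within one voxel)."""
        import warnings
        from roifc.ica import (concat_and_reduce, group_roi_set,
                               match_components)
        from roifc.preprocess import preprocess_run
        from roifc.study import _subject_zmaps
        from roifc.synthetic import (ellipsoid_mask, generate_cohort,
                                     battery_nodes, template_network_maps)
        tpl = two_network_templates()
        cfg = CohortConfig(n_subjects=8, grid_shape=GRID, jitter_sd_mm=0.0,
                           noise_sd=1.0, n_timepoints=80, seed=21,
                           coupling={})
        runs, _ = generate_cohort(tpl, cfg)
        for r in runs:
            r.data = preprocess_run(r, small_mask).data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cs = concat_and_reduce(runs, small_mask, 6, seed=0)
        comp = match_components(cs, template_network_maps(tpl, GRID, VOXEL))
        nodes = battery_nodes(tpl, search_radius_mm=14.0)
        grp = group_roi_set(cs, nodes, comp)
        centers = {r.label: r.center_voxel for r in grp}
        dists = []
        for run in runs:
            ss = subject_roi_set(_subject_zmaps(run, cs, comp, small_mask),
                                 nodes, small_mask)
            for roi in ss:
                dists.append(np.linalg.norm(
                    (roi.center_voxel - centers[roi.label]).astype(float)))
        assert np.median(dists) <= 1.0 + 1e-9
        assert max(dists) <= 3.0

    def test_different_jitters_give_different_batteries(self, small_analysis):
        from roifc.study import _subject_zmaps
        cs = small_analysis["cs"]
        mask = small_analysis["mask"]
        runs = small_analysis["runs"]
        sets = []
        for run in runs[:2]:
            zmaps = _subject_zmaps(run, cs, small_analysis["component_of"],
                                   mask)
            sets.append(subject_roi_set(zmaps, small_analysis["nodes"], mask))
        centers = [np.stack([r.center_voxel for r in s]) for s in sets]
        assert not np.array_equal(centers[0], centers[1])
        assert sets[0].method == "subject_specific"


class TestLiteratureRoiSet:
    def _mask(self):
        return np.ones((11, 11, 11), dtype=bool)

    def _nodes(self):
        return [NodeSpec("N", "a", (10, 10, 10)), NodeSpec("N", "b", (4, 6, 8))]

    def test_exact_voxel_center_is_kept(self):
        rs = literature_roi_set({"N.a": (10, 10, 10), "N.b": (4, 6, 8)},
                                self._nodes(), self._mask(), AFF)
        assert tuple(rs.roi("N.a").center_voxel) == (5, 5, 5)
        assert tuple(rs.roi("N.b").center_voxel) == (2, 3, 4)

    def test_midpoint_resolves_to_lower_voxel(self):
        rs = literature_roi_set({"N.a": (9.0, 10, 10), "N.b": (4, 6, 8)},
                                self._nodes(), self._mask(), AFF)
        assert tuple(rs.roi("N.a").center_voxel) == (4, 5, 5)

    def test_identical_across_subjects(self):
        coords = {"N.a": (10, 10, 10), "N.b": (4, 6, 8)}
        a = literature_roi_set(coords, self._nodes(), self._mask(), AFF)
        b = literature_roi_set(coords, self._nodes(), self._mask(), AFF)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.voxels, rb.voxels)

    def test_out_of_mask_coordinate_names_node(self):
        mask = self._mask()
        mask[2, 3, 4] = False
        with pytest.raises(GridError, match="N.b"):
            literature_roi_set({"N.a": (10, 10, 10), "N.b": (4, 6, 8)},
                               self._nodes(), mask, AFF)

    def test_missing_coordinate_rejected(self):
        with pytest.raises(KeyError, match="N.b"):
            literature_roi_set({"N.a": (10, 10, 10)}, self._nodes(),
                               self._mask(), AFF)


def _cube_roi(center, mask=None, edge=6.0, shape=(15, 15, 15)):
    from roifc.core import make_cube_roi
    node = NodeSpec("N", "x", tuple(np.asarray(center) * 2.0))
    return make_cube_roi(node, center, edge, shape, AFF, mask)


class TestRoiStatistics:
    def test_constant_map_mean(self):
        sm = StatMap(values=np.full((15, 15, 15), 3.25), affine=AFF)
        assert roi_mean_zstat(sm, _cube_roi((7, 7, 7))) == 3.25

    def test_single_voxel_roi(self):
        vals = np.zeros((15, 15, 15))
        vals[7, 7, 7] = 5.5
        sm = StatMap(values=vals, affine=AFF)
        assert roi_mean_zstat(sm, _cube_roi((7, 7, 7), edge=2.0)) == 5.5

    def test_mean_z_declines_monotonically_with_displacement(self):
        """On a Gaussian-blob map the ROI mean z never increases as the ROI
        centre moves away from the blob centre."""
        idx = np.indices((15, 15, 15), dtype=float) * 2.0
        blob = np.exp(-(((idx - 14.0) ** 2).sum(axis=0)) / (2 * 6.0 ** 2))
        sm = StatMap(values=10 * blob, affine=AFF)
        means = [roi_mean_zstat(sm, _cube_roi((7 + d, 7, 7)))
                 for d in range(0, 6)]
        assert np.all(np.diff(means) < 0)

    def test_fraction_above_threshold(self):
        vals = np.zeros((15, 15, 15))
        sm = StatMap(values=vals, affine=AFF)
        roi = _cube_roi((7, 7, 7))
        assert roi_in_network(sm, roi) == 0.0
        sm_hi = StatMap(values=np.full((15, 15, 15), 5.0), affine=AFF)
        assert roi_in_network(sm_hi, roi) == 1.0

    def test_fraction_matches_counting_oracle(self):
        vals = np.zeros((15, 15, 15))
        vals[8:, :, :] = 3.0          # suprathreshold half-space
        sm = StatMap(values=vals, affine=AFF)
        roi = _cube_roi((7, 7, 7))
        count = sum(1 for v in roi.voxels if vals[tuple(v)] > 2.3)
        assert roi_in_network(sm, roi) == count / len(roi.voxels)
        assert roi_in_network(sm, roi) == pytest.approx(9 / 27)

    def test_empty_roi_rejected(self):
        sm = StatMap(values=np.zeros((15, 15, 15)), affine=AFF)
        roi = _cube_roi((7, 7, 7))
        roi.voxels = np.empty((0, 3), dtype=int)
        with pytest.raises(ValueError, match="N.x"):
            roi_mean_zstat(sm, roi)
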