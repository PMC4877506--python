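"""Virtual-dissection stages against phantom ground truth."""

import numpy as np
import pandas as pd
import pytest

from stemtract import dissection, phantom
from stemtract.dissection import (ExtractionRules, PrepParams, StemROI,
                                  classify_streamline, expose_stem,
                                  extract_tract, prepare_tractogram,
                                  streamline_length, suggest_stem_slice)
from stemtract.geometry import nearest_voxel, sample_polyline_points
from stemtract.tract_io import Tractogram


def make_cohort(**kw):
    defaults = dict(n_subjects=1, seed=13)
    defaults.update(kw)
    return phantom.CohortSpec(**defaults)


def test_streamline_length_examples():
    assert streamline_length([[0, 0, 0], [0, 3, 0]]) == 3.0
    assert streamline_length([[0, 0, 0], [1, 0, 0], [1, 1, 0]]) == \
        pytest.approx(2.0)


class TestClassify:
    def test_u_fiber_never_enters_dwm(self, small_subject, atlas, dilated):
        _, t, truth = small_subject
        idx = truth.frame.index[truth.frame.true_class == "u_fiber"][:5]
        for i in idx:
            c = classify_streamline(t.streamlines[i], atlas, dilated)
            assert c.tissues <= {"CGM", "SWM"}
            assert "DWM" not in c.tissues

    def test_interhemispheric_crosses_midline(self, small_subject, atlas,
                                              dilated):
        _, t, truth = small_subject
        tf = truth.frame
        for i in tf.index[tf.true_class == "interhemispheric"][:5]:
            c = classify_streamline(t.streamlines[i], atlas, dilated)
            assert c.crosses_midsagittal
        for i in tf.index[tf.true_class == "tract_whole"][:5]:
            c = classify_streamline(t.streamlines[i], atlas, dilated)
            assert not c.crosses_midsagittal

    def test_traversal_matches_fine_sampling(self, small_subject, atlas,
                                             dilated):
        """Exact-walk tissue sets vs 0.1 mm polyline sampling."""
        _, t, truth = small_subject
        tissue_lut = atlas.table.lookup_array("tissue", fill="")
        rng = np.random.default_rng(0)
        pick = rng.choice(len(t), 50, replace=False)
        for i in pick:
            s = t.streamlines[i]
            c = classify_streamline(s, atlas, dilated)
            dense = sample_polyline_points(s, 0.1)
            labs = atlas.labels_at_voxels(nearest_voxel(dense, atlas.affine))
            sampled = set(tissue_lut[labs[labs != 0]])
            assert sampled <= set(c.tissues)
            assert set(c.tissues) - sampled == set()


class TestPrepare:
    def test_phantom_tally_is_exact(self, atlas, dilated, spec):
        cohort = make_cohort(decoys={
            "short": 50, "gm_confined": 40, "u_fiber": 30,
            "cerebellar": 20, "interhemispheric": 10, "stem_bypass": 0})
        t, truth = phantom.simulate_subject(atlas, cohort, 0, spec)
        res = prepare_tractogram(t, atlas, dilated, PrepParams())
        assert res.tally == {"short": 50, "gm_confined": 40, "u_fiber": 30,
                             "cerebellar": 20, "interhemispheric": 10}
        survivors = set(res.kept_indices)
        tract = set(truth.frame.index[
            truth.frame.true_class.isin(["tract_whole", "tract_broken"])])
        assert survivors == tract

    def test_tally_partitions_input(self, small_subject, atlas, dilated):
        _, t, _ = small_subject
        res = prepare_tractogram(t, atlas, dilated)
        assert sum(res.tally.values()) + len(res.tractogram) == len(t)
        removed = res.removal_rule != ""
        assert removed.sum() == sum(res.tally.values())

    def test_pure_tract_removes_nothing(self, atlas, dilated, spec):
        cohort = make_cohort(decoys={}, broken_fraction=0.0)
        t, _ = phantom.simulate_subject(atlas, cohort, 0, spec)
        res = prepare_tractogram(t, atlas, dilated)
        assert sum(res.tally.values()) == 0
        assert len(res.tractogram) == len(t)

    def test_empty_tractogram(self, atlas, dilated):
        res = prepare_tractogram(Tractogram([], affine=atlas.affine),
                                 atlas, dilated)
        assert len(res.tractogram) == 0
        assert all(v == 0 for v in res.tally.values())


class TestExpose:
    def insula_streamline(self, spec, hemi):
        """DWM streamline ending inside the insular block."""
        blk = spec.insula_block(hemi)
        end = np.array([(blk[0] + 1) * 2.0 - 59, (blk[2] + 5) * 2.0 - 71,
                        (blk[4] + 4) * 2.0 - 59])
        sign = 1.0 if hemi == "right" else -1.0
        start = np.array([sign * 22.0, 30.0, 30.0])
        n = 40
        return start + np.linspace(0, 1, n)[:, None] * (end - start)

    def test_insula_decoys_removed_bundle_intact(self, atlas, dilated, spec):
        tracts = {"IFOF": phantom._default_tracts()["IFOF"]}
        cohort = make_cohort(decoys={}, broken_fraction=0.0, tracts=tracts)
        t, truth = phantom.simulate_subject(atlas, cohort, 0, spec)
        decoys = [self.insula_streamline(spec, h)
                  for h in ("left", "right") for _ in range(10)]
        mixed = Tractogram(list(t.streamlines) + decoys, affine=t.affine,
                           voxel_size=t.voxel_size)
        exposed = expose_stem(mixed, dilated, "IFOF")
        assert len(exposed) == len(t)

    def test_identity_when_no_shrouding_endpoints(self, atlas, dilated, spec):
        tracts = {"IFOF": phantom._default_tracts()["IFOF"]}
        cohort = make_cohort(decoys={}, broken_fraction=0.0, tracts=tracts)
        t, _ = phantom.simulate_subject(atlas, cohort, 0, spec)
        assert len(expose_stem(t, dilated, "IFOF")) == len(t)

    def test_uf_exposure_empties_stg_terminating_set(self, atlas, dilated,
                                                     spec):
        tracts = {"UF": phantom.TractSpec(
            name="UF", orientation="axial", n_streamlines={"right": 20},
            anterior_probs={"right": {"orbito_frontal": 1.0}},
            posterior_probs={"right": {"superior_temporal": 1.0}})}
        cohort = make_cohort(decoys={}, broken_fraction=0.0, tracts=tracts)
        t, _ = phantom.simulate_subject(atlas, cohort, 0, spec)
        assert len(expose_stem(t, dilated, "UF")) == 0

    def test_unknown_tract_errors(self, small_subject, dilated):
        _, t, _ = small_subject
        with pytest.raises(ValueError, match="unknown tract"):
            expose_stem(t, dilated, "ARC")


class TestSuggestStem:
    def test_finds_designed_waist(self, atlas, spec):
        tracts = {"IFOF": phantom._default_tracts()["IFOF"]}
        cohort = make_cohort(decoys={}, broken_fraction=0.0, tracts=tracts)
        t, truth = phantom.simulate_subject(atlas, cohort, 0, spec)
        right = t.subset(truth.frame.index[truth.frame.hemisphere == "right"])
        jm = spec.stem_mask_voxels("IFOF", "right")[0, 1]
        idx, mask, profile = suggest_stem_slice(
            right, atlas, "coronal", range(jm - 6, jm + 7))
        assert idx == jm
        expected = set(map(tuple, spec.stem_mask_voxels("IFOF", "right")))
        assert set(map(tuple, np.argwhere(mask))) == expected
        assert profile.n_voxels.min() == 4

    def test_tie_breaks_to_lower_slice(self, atlas):
        # one straight streamline along y: every slice width 1 -> lowest wins
        s = np.c_[np.full(40, 1.0), np.linspace(-30, 30, 40), np.zeros(40)]
        t = Tractogram([s], affine=atlas.affine, voxel_size=atlas.voxel_size)
        idx, mask, profile = suggest_stem_slice(t, atlas, "coronal",
                                                range(25, 36))
        assert idx == 25
        assert int(mask.sum()) == 1
        assert (profile.n_voxels == 1).all()

    def test_empty_range_errors(self, small_subject, atlas):
        _, t, _ = small_subject
        with pytest.raises(ValueError, match="search range"):
            suggest_stem_slice(t, atlas, "coronal", [])


class TestExtract:
    def test_bypass_decoys_not_kept(self, atlas, dilated, spec,
                                    stem_roi_factory):
        tracts = {"IFOF": phantom._default_tracts()["IFOF"]}
        cohort = make_cohort(decoys={"stem_bypass": 50}, broken_fraction=0.0,
                             tracts=tracts)
        t, truth = phantom.simulate_subject(atlas, cohort, 0, spec)
        kept = set()
        for hemi in ("left", "right"):
            res = extract_tract(t, stem_roi_factory("IFOF", hemi),
                                ExtractionRules(), atlas, dilated)
            kept |= set(res.endpoints.orig_index)
        tf = truth.frame
        assert kept == set(tf.index[tf.true_class == "tract_whole"])

    def test_posterior_exclusion_plane_is_identity_for_anterior_bundle(
            self, atlas, dilated, spec, stem_roi_factory):
        tracts = {"IFOF": phantom.TractSpec(
            name="IFOF", orientation="coronal", n_streamlines={"right": 30},
            anterior_probs={"right": {"inferior_frontal": 1.0}},
            posterior_probs={"right": {"middle_occipital": 1.0}})}
        cohort = make_cohort(decoys={}, broken_fraction=0.0, tracts=tracts)
        t, _ = phantom.simulate_subject(atlas, cohort, 0, spec)
        roi = stem_roi_factory("IFOF", "right")
        plain = extract_tract(t, roi, ExtractionRules(), atlas, dilated)
        # posterior CGM bank ends near y = -63; plane just beyond it
        ruled = extract_tract(
            t, roi, ExtractionRules(exclusion_plane=("y", -70.0, "less")),
            atlas, dilated)
        assert ruled.tally == plain.tally
        assert len(ruled.tractogram) == 30
        # a plane that cuts the posterior bank removes everything
        cut = extract_tract(
            t, roi, ExtractionRules(exclusion_plane=("y", -20.0, "less")),
            atlas, dilated)
        assert cut.tally["kept"] == 0
        assert cut.tally["excluded_by_plane"] == 30

    def test_exclusion_labels_drop_traversers(self, atlas, dilated, spec,
                                              stem_roi_factory):
        tracts = {"UF": phantom._default_tracts()["UF"]}
        cohort = make_cohort(decoys={}, broken_fraction=0.0, tracts=tracts)
        t, truth = phantom.simulate_subject(atlas, cohort, 0, spec)
        names = atlas.table.frame.name.astype(str)
        tp = set(atlas.table.frame.index[names.str.startswith("temporal_pole")])
        res = extract_tract(t, stem_roi_factory("UF", "right"),
                            ExtractionRules(exclusion_labels=tp),
                            atlas, dilated)
        tf = truth.frame
        tp_ids = {phantom.label_id("temporal_pole", "right")}
        expected = set(tf.index[(tf.hemisphere == "right")
                                & ~tf.posterior_label.isin(tp_ids)])
        assert set(res.endpoints.orig_index) == expected
        assert res.tally["excluded_by_label"] == \
            (tf[tf.hemisphere == "right"].posterior_label.isin(tp_ids)).sum()

    def test_broken_counts_follow_per_end_breakage(self, atlas, dilated,
                                                   spec, stem_roi_factory):
        f = 0.2
        tracts = {"IFOF": phantom._default_tracts()["IFOF"]}
        tracts["IFOF"].n_streamlines = {"right": 1000}
        cohort = make_cohort(decoys={}, broken_fraction=f, tracts=tracts,
                             seed=29)
        t, truth = phantom.simulate_subject(atlas, cohort, 0, spec)
        res = extract_tract(t, stem_roi_factory("IFOF", "right"),
                            ExtractionRules(), atlas, dilated)
        assert res.tally["kept"] == 1000           # breakage spares the stem
        n_broken_true = (truth.frame.true_class == "tract_broken").sum()
        assert res.tally["broken"] == n_broken_true
        p = 1 - (1 - f) ** 2
        assert abs(res.tally["broken"] - p * 1000) <= \
            3 * np.sqrt(p * (1 - p) * 1000)
        ep = res.endpoints
        flagged = set(ep.orig_index[ep.broken])
        truth_broken = set(truth.frame.index[
            truth.frame.true_class == "tract_broken"])
        assert flagged == truth_broken

    def test_discard_broken_drops_them(self, atlas, dilated, spec,
                                       stem_roi_factory):
        tracts = {"IFOF": phantom._default_tracts()["IFOF"]}
        cohort = make_cohort(decoys={}, broken_fraction=0.3, tracts=tracts)
        t, truth = phantom.simulate_subject(atlas, cohort, 0, spec)
        res = extract_tract(t, stem_roi_factory("IFOF", "right"),
                            ExtractionRules(discard_broken=True),
                            atlas, dilated)
        tf = truth.frame
        whole_right = set(tf.index[(tf.true_class == "tract_whole")
                                   & (tf.hemisphere == "right")])
        assert set(res.endpoints.orig_index) == whole_right

    def test_order_invariance(self, atlas, dilated, spec, stem_roi_factory):
        cohort = make_cohort(seed=31)
        t, _ = phantom.simulate_subject(atlas, cohort, 0, spec)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(t))
        shuffled = t.subset(perm)
        roi = stem_roi_factory("IFOF", "left")
        a = extract_tract(t, roi, ExtractionRules(), atlas, dilated)
        b = extract_tract(shuffled, roi, ExtractionRules(), atlas, dilated)
        assert a.tally == b.tally
        orig_of_shuffled = {perm[r.orig_index] for r in
                            b.endpoints.itertuples()}
        assert orig_of_shuffled == set(a.endpoints.orig_index)

    def test_extraction_superset_of_prepared_extraction(
            self, small_subject, atlas, dilated, stem_roi_factory):
        """Original-tractogram extraction restricted to prepared survivors
        equals extraction from the prepared tractogram."""
        _, t, _ = small_subject
        prep = prepare_tractogram(t, atlas, dilated)
        roi = stem_roi_factory("UF", "left")
        from_original = extract_tract(t, roi, ExtractionRules(), atlas,
                                      dilated)
        from_prepared = extract_tract(prep.tractogram, roi,
                                      ExtractionRules(), atlas, dilated)
        orig_kept = set(from_original.endpoints.orig_index)
        prepared_kept = {prep.kept_indices[i]
                         for i in from_prepared.endpoints.orig_index}
        assert prepared_kept <= orig_kept
        assert orig_kept & set(prep.kept_indices) == prepared_kept

    def test_empty_stem_mask_errors(self, atlas):
        with pytest.raises(ValueError, match="empty"):
            StemROI(np.zeros((4, 4, 4), dtype=bool), np.eye(4), "coronal")

    def test_multi_slice_mask_rejected(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1, 1, 1] = m[1, 2, 1] = True
        with pytest.raises(ValueError, match="single-slice"):
            StemROI(m, np.eye(4), "coronal")
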