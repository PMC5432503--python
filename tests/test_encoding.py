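"""Forward encoding model: weights, inversion, CTFs, reconstruction."""

import numpy as np
import pytest

from ctfeeg import decoding, encoding
from ctfeeg.decoding import ActivationPattern
from ctfeeg.synthgen import circular_gaussian_profile


class TestBasisAndDesign:
    def test_delta_basis_is_identity(self):
        basis = encoding.BasisSet.delta(8)
        np.testing.assert_array_equal(basis.matrix, np.eye(8))
        assert basis.kind == "delta"

    def test_design_columns_are_basis_columns(self):
        design = encoding.build_design(np.array([1, 3]),
                                       encoding.BasisSet.delta(4))
        np.testing.assert_array_equal(design.C1[:, 0], [1, 0, 0, 0])
        np.testing.assert_array_equal(design.C1[:, 1], [0, 0, 1, 0])

    def test_row_sums_equal_class_counts(self):
        labels = np.repeat(np.arange(1, 9), [3, 1, 4, 2, 2, 5, 1, 2])
        design = encoding.build_design(labels, encoding.BasisSet.delta(8))
        np.testing.assert_array_equal(design.C1.sum(axis=1),
                                      [3, 1, 4, 2, 2, 5, 1, 2])

    def test_custom_basis_stored_verbatim(self):
        mat = circular_gaussian_profile(6, 1.0)
        basis = encoding.BasisSet(mat, kind="custom")
        design = encoding.build_design(np.array([2, 5]), basis)
        np.testing.assert_array_equal(design.C1[:, 0], mat[:, 1])

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            encoding.build_design(np.array([1, 9]), encoding.BasisSet.delta(8))


class TestEstimateWeights:
    def test_delta_weights_equal_per_class_means(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 5, size=60)
        labels[:4] = [1, 2, 3, 4]  # all classes present
        b1 = rng.normal(size=(7, 60))
        design = encoding.build_design(labels, encoding.BasisSet.delta(4))
        model = encoding.estimate_weights(b1, design)
        for p in range(1, 5):
            np.testing.assert_allclose(model.W[:, p - 1],
                                       b1[:, labels == p].mean(axis=1),
                                       atol=1e-10)

    def test_single_trial_per_class_interpolates_exactly(self):
        rng = np.random.default_rng(1)
        b1 = rng.normal(size=(5, 3))
        design = encoding.build_design(np.array([1, 2, 3]),
                                       encoding.BasisSet.delta(3))
        model = encoding.estimate_weights(b1, design)
        np.testing.assert_allclose(model.W @ design.C1, b1, atol=1e-10)

    def test_linearity_in_data(self):
        rng = np.random.default_rng(2)
        labels = np.repeat([1, 2, 3], 10)
        b1 = rng.normal(size=(6, 30))
        design = encoding.build_design(labels, encoding.BasisSet.delta(3))
        w1 = encoding.estimate_weights(b1, design).W
        w2 = encoding.estimate_weights(2 * b1, design).W
        np.testing.assert_allclose(w2, 2 * w1, atol=1e-10)

    def test_missing_class_named_in_error(self):
        labels = np.array([1, 1, 2, 2])  # class 3 absent
        design = encoding.build_design(labels, encoding.BasisSet.delta(3))
        with pytest.raises(ValueError, match=r"missing classes: \[3\]"):
            encoding.estimate_weights(np.zeros((4, 4)), design)


class TestInversion:
    def test_noise_free_round_trip_recovers_channel_responses(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=(10, 4))
        c = rng.normal(size=(4, 20))
        model = encoding.EncodingModel(W=w)
        resp = encoding.invert_model(model, w @ c)
        np.testing.assert_allclose(resp.C2, c, atol=1e-10)

    def test_signal_orthogonal_to_weights_gives_zero_response(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=(10, 3))
        q, _ = np.linalg.qr(np.c_[w, rng.normal(size=(10, 7))])
        ortho = q[:, 3:]  # orthogonal complement of col(w)
        resp = encoding.invert_model(encoding.EncodingModel(W=w),
                                     ortho @ rng.normal(size=(7, 5)))
        np.testing.assert_allclose(resp.C2, 0.0, atol=1e-9)

    def test_condition_means_peak_at_labeled_channel(self, small_sim):
        # cycle through every fold at the signal peak so each trial is
        # tested once, then average channel responses per condition
        cfg, epochs, _ = small_sim
        folds = decoding.assign_folds(epochs.labels, 10, seed=2)
        sl = epochs.time_slice((240.0, 290.0))
        c2 = np.zeros((8, epochs.n_trials))
        for train, test in folds.split():
            design = encoding.build_design(epochs.labels[train],
                                           encoding.BasisSet.delta(8))
            for ti in range(sl.start, sl.stop):
                model = encoding.estimate_weights(
                    epochs.data[train, :, ti].T, design)
                c2[:, test] += encoding.invert_model(
                    model, epochs.data[test, :, ti].T).C2
        c2 /= sl.stop - sl.start
        means = encoding.ChannelResponses(C2=c2,
                                          labels=epochs.labels).condition_means()
        peaks = np.argmax(means, axis=0)
        # most conditions peak at their own channel; any miss lands on an
        # immediate neighbour (the tuning profile overlaps adjacent channels)
        assert np.sum(peaks == np.arange(8)) >= 5
        circ_err = np.minimum((peaks - np.arange(8)) % 8,
                              (np.arange(8) - peaks) % 8)
        assert circ_err.max() <= 1

    def test_rank_deficient_weights_rejected_with_condition_report(self):
        w = np.ones((6, 3))  # identical columns
        with pytest.raises(ValueError, match="condition number"):
            encoding.invert_model(encoding.EncodingModel(W=w), np.ones((6, 4)))


class TestCanonicalCtf:
    def _responses(self, profile, k=8):
        """One trial per condition whose response is the condition's own
        profile (peak at its labeled channel)."""
        c2 = np.column_stack([np.roll(profile, p) for p in range(k)])
        return encoding.ChannelResponses(C2=c2,
                                         labels=np.arange(1, k + 1))

    def test_identical_bumps_align_to_center(self):
        profile = np.roll(circular_gaussian_profile(8, 1.0)[:, 0], 0)
        ctf = encoding.canonical_ctf(self._responses(profile), center=4)
        expected = np.roll(profile, 3)  # bump centered at channel 4
        np.testing.assert_allclose(ctf.aligned, expected, atol=1e-12)
        assert np.argmax(ctf.aligned) == 3

    def test_condition_order_invariance(self):
        rng = np.random.default_rng(5)
        c2 = rng.normal(size=(8, 40))
        labels = np.repeat(np.arange(1, 9), 5)
        perm = rng.permutation(40)
        a = encoding.canonical_ctf(
            encoding.ChannelResponses(C2=c2, labels=labels))
        b = encoding.canonical_ctf(
            encoding.ChannelResponses(C2=c2[:, perm], labels=labels[perm]))
        np.testing.assert_allclose(a.aligned, b.aligned, atol=1e-12)

    def test_joint_circular_shift_equivariance(self):
        rng = np.random.default_rng(6)
        c2 = rng.normal(size=(8, 16))
        labels = np.repeat(np.arange(1, 9), 2)
        base = encoding.canonical_ctf(
            encoding.ChannelResponses(C2=c2, labels=labels))
        shifted_labels = labels % 8 + 1
        shifted_c2 = np.roll(c2, 1, axis=0)
        shifted = encoding.canonical_ctf(
            encoding.ChannelResponses(C2=shifted_c2, labels=shifted_labels))
        np.testing.assert_allclose(shifted.aligned, base.aligned, atol=1e-12)

    def test_alignment_conserves_channel_sum(self):
        rng = np.random.default_rng(7)
        c2 = rng.normal(size=(8, 24))
        labels = np.repeat(np.arange(1, 9), 3)
        resp = encoding.ChannelResponses(C2=c2, labels=labels)
        ctf = encoding.canonical_ctf(resp)
        np.testing.assert_allclose(ctf.aligned.sum(),
                                   resp.condition_means().mean(axis=1).sum(),
                                   atol=1e-12)

    def test_invalid_center_rejected(self):
        resp = encoding.ChannelResponses(C2=np.zeros((4, 4)),
                                         labels=np.arange(1, 5))
        with pytest.raises(ValueError, match="center"):
            encoding.canonical_ctf(resp, center=9)

    def test_display_variant_appends_wraparound_channel(self):
        profile = circular_gaussian_profile(8, 1.0)[:, 0]
        ctf = encoding.canonical_ctf(self._responses(profile), center=4)
        disp = ctf.display_values()
        assert disp.shape == (9,)
        assert disp[-1] == ctf.aligned[(3 + 4) % 8]


class TestCtfTimecourse:
    def test_noise_free_signal_sample_recovers_delta_profile(self,
                                                             noisefree_sim):
        # with exact per-class-mean weights the OLS inversion returns the
        # exact-interpolation delta profile at the centre channel (the
        # graded CTF shape is a finite-noise phenomenon); pre-stimulus
        # samples are identically zero here, so the model is degenerate
        # outside the signal window and the full time course must raise
        cfg, epochs, _ = noisefree_sim
        folds = decoding.assign_folds(epochs.labels, 5, seed=3)
        peak = epochs.time_index(cfg.signal_peak)
        c2 = np.empty((8, epochs.n_trials))
        for train, test in folds.split():
            design = encoding.build_design(epochs.labels[train],
                                           encoding.BasisSet.delta(8))
            model = encoding.estimate_weights(epochs.data[train, :, peak].T,
                                              design)
            c2[:, test] = encoding.invert_model(
                model, epochs.data[test, :, peak].T).C2
        ctf = encoding.canonical_ctf(
            encoding.ChannelResponses(C2=c2, labels=epochs.labels), center=4)
        expected = np.zeros(8)
        expected[3] = 1.0
        np.testing.assert_allclose(ctf.aligned, expected, atol=1e-8)
        with pytest.raises(ValueError, match="rank-deficient"):
            encoding.ctf_timecourse(epochs, folds)

    def test_prestimulus_window_is_flat(self, small_sim):
        _, epochs, _ = small_sim
        folds = decoding.assign_folds(epochs.labels, 10, seed=4)
        ctf = encoding.ctf_timecourse(epochs, folds)
        pre = ctf.average_window((-100.0, -10.0))
        spread = pre.aligned.max() - pre.aligned.min()
        post = ctf.average_window((240.0, 290.0))
        assert spread < 0.3 * (post.aligned.max() - post.aligned.min())
        assert np.argmax(post.aligned) == 3

    def test_seeded_run_reproducible(self, small_sim):
        _, epochs, _ = small_sim
        folds = decoding.assign_folds(epochs.labels, 10, seed=5)
        a = encoding.ctf_timecourse(epochs, folds)
        b = encoding.ctf_timecourse(epochs, folds)
        np.testing.assert_array_equal(a.aligned, b.aligned)
        np.testing.assert_array_equal(a.weights, b.weights)


class TestTuningStat:
    def test_center_equal_edge_gives_zero_t(self):
        ctfs = np.tile(np.ones((1, 8, 1)), (5, 1, 10))
        t, _ = encoding.ctf_tuning_stat(ctfs, center=4)
        np.testing.assert_allclose(t, 0.0)

    def test_constant_positive_difference_flagged_infinite(self):
        ctfs = np.zeros((4, 8, 6))
        ctfs[:, 3, :] = 1.0  # centre channel above edge, zero variance
        t, _ = encoding.ctf_tuning_stat(ctfs, center=4)
        assert np.all(np.isinf(t)) and np.all(t > 0)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            encoding.ctf_tuning_stat(np.zeros((1, 8, 5)))

    def test_tuned_subjects_produce_significant_cluster(self):
        from ctfeeg import stats

        rng = np.random.default_rng(8)
        n_subj, n_t = 10, 40
        profile = circular_gaussian_profile(8, 1.2)[:, 3]
        ctfs = 0.05 * rng.normal(size=(n_subj, 8, n_t))
        ctfs[:, :, 15:30] += 0.5 * profile[None, :, None]
        t, _ = encoding.ctf_tuning_stat(ctfs, center=4)
        diff = ctfs[:, 3, :] - ctfs[:, 7, :]
        res = stats.cluster_permutation_time(diff, 0.0, n_perm=500, seed=0)
        sig = res.significant(0.05)
        assert len(sig) >= 1
        lo, hi = sig[0].bounds()
        assert lo >= 13 and hi <= 32


class TestSymmetryAndInterpolation:
    def _gaussian_ctf(self, width=1.2, center=4):
        vals = circular_gaussian_profile(8, width)[:, center - 1]
        return encoding.ChannelTuningFunction(aligned=vals, center=center)

    def test_symmetrization_of_symmetric_profile_is_identity(self):
        ctf = self._gaussian_ctf()
        np.testing.assert_allclose(ctf.symmetrized(), ctf.aligned, atol=1e-12)

    def test_symmetrized_profile_is_mirror_invariant(self):
        rng = np.random.default_rng(9)
        ctf = encoding.ChannelTuningFunction(aligned=rng.normal(size=8),
                                             center=4)
        sym = ctf.symmetrized()
        mirror = sym[(2 * 3 - np.arange(8)) % 8]
        np.testing.assert_allclose(sym, mirror, atol=1e-12)

    def test_hypothetical_response_recenters_ctf(self):
        ctf = self._gaussian_ctf()
        hyp = encoding.hypothetical_responses(ctf)
        for p in range(1, 9):
            assert np.argmax(hyp[:, p - 1]) == p - 1
            np.testing.assert_allclose(hyp[:, p - 1],
                                       np.roll(ctf.aligned, p - 4),
                                       atol=1e-12)

    def test_midpoint_tag_averages_neighbor_vectors(self):
        ctf = self._gaussian_ctf()
        hyp = encoding.hypothetical_responses(ctf)
        top = encoding.interpolate_channel_response(ctf, "top")
        np.testing.assert_allclose(top, 0.5 * (hyp[:, 7] + hyp[:, 0]),
                                   atol=1e-12)

    def test_degenerate_weight_returns_neighbor_exactly(self):
        ctf = self._gaussian_ctf()
        angles = np.array([22.5 + 45.0 * i for i in range(8)])
        hyp = encoding.hypothetical_responses(ctf)
        got = encoding.interpolate_channel_response(ctf, 67.5,
                                                    position_angles=angles)
        np.testing.assert_allclose(got, hyp[:, 1], atol=1e-12)

    def test_angle_midpoint_matches_tag(self):
        ctf = self._gaussian_ctf()
        angles = np.array([22.5 + 45.0 * i for i in range(8)])
        by_tag = encoding.interpolate_channel_response(ctf, "top")
        by_angle = encoding.interpolate_channel_response(
            ctf, 0.0, position_angles=angles)
        np.testing.assert_allclose(by_angle, by_tag, atol=1e-12)

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="midpoint tag"):
            encoding.interpolate_channel_response(self._gaussian_ctf(),
                                                  "diagonal")


class TestReconstruction:
    def test_delta_response_returns_weight_column(self):
        rng = np.random.default_rng(10)
        w = rng.normal(size=(9, 8))
        e3 = np.zeros(8)
        e3[2] = 1.0
        pattern = encoding.reconstruct_topography(
            encoding.EncodingModel(W=w), e3)
        np.testing.assert_allclose(pattern.values, w[:, 2])

    def test_linearity(self):
        rng = np.random.default_rng(11)
        w = rng.normal(size=(9, 8))
        c1, c2 = rng.normal(size=8), rng.normal(size=8)
        model = encoding.EncodingModel(W=w)
        combo = encoding.reconstruct_topography(model, 2 * c1 - 3 * c2)
        parts = (2 * encoding.reconstruct_topography(model, c1).values
                 - 3 * encoding.reconstruct_topography(model, c2).values)
        np.testing.assert_allclose(combo.values, parts, atol=1e-12)

    def test_contrast_and_normalize_properties(self):
        a = ActivationPattern(np.array([1.0, 2.0, 4.0]), list("abc"))
        b = ActivationPattern(np.array([0.5, 1.0, 1.5]), list("abc"))
        out = encoding.contrast_and_normalize(a, b)
        assert out.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.values.std() == pytest.approx(1.0, abs=1e-12)
        flipped = encoding.contrast_and_normalize(b, a)
        np.testing.assert_allclose(flipped.values, -out.values, atol=1e-12)
        with pytest.raises(ValueError, match="zero spread"):
            encoding.contrast_and_normalize(a, a)

    def test_fit_tuning_width_recovers_exact_gaussian(self):
        for sigma in (0.8, 1.2, 2.0):
            vals = 0.7 * circular_gaussian_profile(8, sigma)[:, 3] + 0.1
            got, a, b = encoding.fit_tuning_width(vals, center=4)
            assert got == pytest.approx(sigma, rel=1e-4)
            assert a == pytest.approx(0.7, rel=1e-3)
            assert b == pytest.approx(0.1, abs=1e-3)


class TestComparePatterns:
    def test_identical_groups_fully_correlated_without_clusters(self,
                                                                exp1_montage):
        rng = np.random.default_rng(12)
        group = rng.normal(size=(6, 23))
        r, clusters = encoding.compare_patterns(group, group,
                                                exp1_montage.adjacency,
                                                n_perm=200, seed=0)
        assert r == pytest.approx(1.0)
        assert len(clusters.significant(0.05)) == 0

    def test_sign_flipped_groups_anticorrelate(self, exp1_montage):
        rng = np.random.default_rng(13)
        group = rng.normal(size=(6, 23)) + 2.0
        r, _ = encoding.compare_patterns(group, -group,
                                         exp1_montage.adjacency,
                                         n_perm=100, seed=0)
        assert r == pytest.approx(-1.0)

    def test_too_few_subjects_rejected(self, exp1_montage):
        with pytest.raises(ValueError, match="2 subjects"):
            encoding.compare_patterns(np.zeros((1, 23)), np.zeros((5, 23)),
                                      exp1_montage.adjacency)
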