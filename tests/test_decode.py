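"""LOSO decoding: classifier correctness, calibration, schemes, searchlight."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import facedecode as fd
from facedecode._fast_lda import FastShrinkageLDA
from facedecode.decode import (ClassifierConfig, SchemeError, _fold_masks,
                               _scheme_folds, adjacency_from_layout,
                               adjacency_matrix, cross_classify_conditions,
                               fit_predict_timepoint, loso_timecourse,
                               roi_map_from_layout, roi_timecourse, scheme,
                               searchlight)
from facedecode.montage import biosemi64, layout_for
from facedecode.synth import CohortConfig, EffectSpec, generate_cohort, posterior_topography


class TestClassifier:
    def test_separable_classes_perfect(self, rng):
        x0 = rng.normal([-4, 0], 0.3, size=(40, 2))
        x1 = rng.normal([4, 0], 0.3, size=(40, 2))
        x = np.vstack([x0, x1])
        y = np.repeat(["a", "b"], 40)
        acc = fit_predict_timepoint(x, y, x, y)
        assert acc == 1.0

    def test_shuffled_labels_at_chance(self, rng):
        accs = []
        for _ in range(30):
            x = rng.standard_normal((80, 6))
            y = rng.permutation(np.repeat([0, 1], 40))
            xt = rng.standard_normal((40, 6))
            yt = rng.permutation(np.repeat([0, 1], 20))
            accs.append(fit_predict_timepoint(x, y, xt, yt))
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) < 3 * se + 1e-9

    def test_matches_closed_form_discriminant(self, rng):
        """Without shrinkage the rule is w = Sigma^-1 (mu1 - mu0) at midpoint."""
        x0 = rng.multivariate_normal([0, 0], [[2, 0.5], [0.5, 1]], size=60)
        x1 = rng.multivariate_normal([1.5, 1.0], [[2, 0.5], [0.5, 1]], size=60)
        x = np.vstack([x0, x1]); y = np.repeat([0, 1], 60)
        xt = rng.standard_normal((200, 2)) * 2
        mu0, mu1 = x0.mean(0), x1.mean(0)
        cov = 0.5 * (np.cov(x0.T, bias=True) + np.cov(x1.T, bias=True))
        w = np.linalg.solve(cov, mu1 - mu0)
        expected = (xt @ w > 0.5 * (mu0 + mu1) @ w).astype(int)
        clf = ClassifierConfig(shrinkage=0.0).make()
        got = clf.fit(x, y).predict(xt)
        assert np.array_equal(got, expected)

    def test_fast_lda_equals_sklearn(self, rng):
        """In-package lsqr+Ledoit-Wolf LDA predicts identically to sklearn."""
        for _ in range(15):
            n, p = int(rng.integers(24, 150)), int(rng.integers(3, 32))
            k = int(rng.choice([2, 4, 8]))
            y = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
            x = rng.standard_normal((n, p)) + y[:, None] * 0.3
            xt = rng.standard_normal((50, p))
            ref = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            assert np.array_equal(FastShrinkageLDA().fit(x, y).predict(xt),
                                  ref.fit(x, y).predict(xt))

    def test_missing_class_named(self):
        x = np.zeros((4, 2)); y = ["a", "a", "b", "b"]
        with pytest.raises(SchemeError, match="happy"):
            fit_predict_timepoint(x, y, x, ["a", "happy", "b", "b"])
        with pytest.raises(SchemeError, match="2 classes"):
            fit_predict_timepoint(x, ["a"] * 4, x, y)


class TestSchemeStructure:
    @pytest.mark.parametrize("target,chance", [
        ("identity", 0.125), ("sex", 0.5), ("emotion", 0.25)])
    def test_chance_levels(self, target, chance):
        assert scheme(target).chance == chance

    def test_pair_scheme_chance(self):
        assert scheme("emotion_pair", ("happy", "neutral")).chance == 0.5

    def test_fold_balance_and_separation(self, noise_pseudo):
        """Training never sees the held-out condition; sex stays 3/3 balanced."""
        md = noise_pseudo.metadata[0]
        for target in ("identity", "sex", "emotion"):
            sp = scheme(target)
            for fold in _scheme_folds(sp, md):
                train, test = _fold_masks(sp, md, fold)
                assert not (train & test).any()
                if target == "identity":
                    assert md.loc[train, "expression"].nunique() == 3
                    assert md.loc[test, "expression"].nunique() == 1
                else:
                    ids = md.loc[train, "identity"]
                    assert ids.nunique() == 6
                    assert fold["held_out_identity"] not in set(ids)
                    assert md.loc[train].groupby("sex")["identity"].nunique().tolist() == [3, 3]

    def test_loso_excludes_test_participant(self, noise_pseudo):
        res = loso_timecourse(noise_pseudo, scheme("identity"))
        # 4 participants x 4 expression folds
        assert res.accuracy.shape[:2] == (4, 4)
        assert {f["held_out_expression"] for f in res.folds} == set(fd.design.EXPRESSIONS)


class TestCalibration:
    @pytest.mark.parametrize("target", ["identity", "sex", "emotion"])
    def test_noise_only_at_chance(self, noise_pseudo, target):
        res = loso_timecourse(noise_pseudo, scheme(target))
        acc = res.accuracy                     # participants x folds x time
        mean = acc.mean(axis=(0, 1))
        # folds share training data, so treat participants as the only
        # independent unit: a conservative Monte-Carlo SE per timepoint
        se = acc.std(axis=(0, 1), ddof=1) / np.sqrt(acc.shape[0])
        assert np.all(np.abs(mean - res.chance) < 3 * se)
        # LOSO folds overlap in training data, so even the grand mean keeps
        # cohort-level Monte-Carlo noise; bound it rather than a per-fold SE
        assert abs(acc.mean() - res.chance) < 0.05
        assert acc.min() >= 0 and acc.max() <= 1

    def test_planted_effect_confined_to_window(self, sex_effect_pseudo):
        res = loso_timecourse(sex_effect_pseudo, scheme("sex"))
        mean = res.participant_timecourse().mean(axis=0)
        t = res.times_ms
        inside = (t >= 30) & (t < 70)
        outside = t < 20
        assert mean[inside].mean() > 0.85
        assert abs(mean[outside].mean() - 0.5) < 0.1

    def test_participant_specific_patterns_not_decodable(self, stim_set):
        eff = EffectSpec(attribute="sex", onset_ms=0, duration_ms=70,
                         amplitude=2.0, shared=False)
        cfg = CohortConfig(n_participants=4, n_channels=8, tmin=-0.025, tmax=0.075,
                           repetitions=6, effects=[eff], seed=13)
        epochs, _ = generate_cohort(cfg, stim_set)
        pseudo = fd.bin_average(epochs, 3, seed=13)
        res = loso_timecourse(pseudo, scheme("sex"))
        pt = res.participant_timecourse()
        se = pt.std(axis=0, ddof=1) / np.sqrt(pt.shape[0])
        assert np.all(np.abs(pt.mean(axis=0) - 0.5) < 3 * se + 0.05)


@pytest.fixture(scope="module")
def identity_effect_pseudo(stim_set):
    """Identity patterns shared across expressions (cross-decodable)."""
    eff = EffectSpec(attribute="identity", onset_ms=0, duration_ms=70, amplitude=2.5)
    cfg = CohortConfig(n_participants=4, n_channels=8, tmin=0.0, tmax=0.075,
                       repetitions=6, effects=[eff], seed=14)
    epochs, _ = generate_cohort(cfg, stim_set)
    return fd.bin_average(epochs, 3, seed=14)


@pytest.fixture(scope="module")
def image_effect_pseudo(stim_set):
    """Image-specific patterns: identity does not generalize across expression."""
    eff = EffectSpec(attribute="image", onset_ms=0, duration_ms=70, amplitude=2.5)
    cfg = CohortConfig(n_participants=4, n_channels=8, tmin=0.0, tmax=0.075,
                       repetitions=6, effects=[eff], seed=15)
    epochs, _ = generate_cohort(cfg, stim_set)
    return fd.bin_average(epochs, 3, seed=15)


class TestCrossClassification:
    def test_symmetric_under_condition_swap(self, identity_effect_pseudo):
        sp = scheme("identity")
        ab = cross_classify_conditions(identity_effect_pseudo, sp, "neutral", "angry")
        ba = cross_classify_conditions(identity_effect_pseudo, sp, "angry", "neutral")
        assert np.allclose(ab.accuracy, ba.accuracy)

    def test_identical_conditions_equal_within_decoding(self, identity_effect_pseudo):
        sp = scheme("identity")
        aa = cross_classify_conditions(identity_effect_pseudo, sp, "neutral", "neutral")
        # both directions are the same computation, so the average equals either
        assert aa.accuracy.min() >= 0.0 and aa.accuracy.max() <= 1.0
        ab = cross_classify_conditions(identity_effect_pseudo, sp, "neutral", "angry")
        assert aa.accuracy.shape == ab.accuracy.shape

    def test_shared_identity_patterns_cross_decode(self, identity_effect_pseudo):
        res = cross_classify_conditions(identity_effect_pseudo, scheme("identity"),
                                        "neutral", "angry")
        assert res.participant_timecourse().mean() > 0.5  # chance 0.125

    def test_image_specific_patterns_do_not_cross_decode(self, image_effect_pseudo):
        res = cross_classify_conditions(image_effect_pseudo, scheme("identity"),
                                        "neutral", "angry")
        pt = res.participant_timecourse()
        se = pt.std(axis=0, ddof=1) / np.sqrt(pt.shape[0])
        assert np.all(np.abs(pt.mean(axis=0) - 0.125) < 3 * se + 0.05)

    def test_empty_condition_rejected(self, identity_effect_pseudo):
        with pytest.raises(SchemeError):
            cross_classify_conditions(identity_effect_pseudo, scheme("identity"),
                                      lambda md: np.zeros(len(md), bool), "angry")


class TestSearchlight:
    def test_universal_adjacency_equals_all_electrode(self, sex_effect_pseudo):
        names = list(sex_effect_pseudo.layout.names)
        adj = {ch: set(names) for ch in names}
        sl = searchlight(sex_effect_pseudo, adj, scheme("sex"))
        full = loso_timecourse(sex_effect_pseudo, scheme("sex"))
        assert sl.accuracy.shape[2] == len(names)
        for c in range(len(names)):
            assert np.allclose(sl.accuracy[:, :, c], full.accuracy)

    def test_localized_effect_peaks_in_planted_support(self, stim_set):
        layout = layout_for(16)
        topo = posterior_topography(layout)
        eff = EffectSpec(attribute="sex", onset_ms=0, duration_ms=50,
                         amplitude=3.0, topography=topo)
        cfg = CohortConfig(n_participants=3, n_channels=16, tmin=0.0, tmax=0.05,
                           repetitions=6, effects=[eff], seed=16)
        epochs, _ = generate_cohort(cfg, stim_set)
        pseudo = fd.bin_average(epochs, 3, seed=16)
        adj = adjacency_from_layout(layout)
        sl = searchlight(pseudo, adj, scheme("sex"))
        chan_mean = sl.accuracy.mean(axis=(0, 1, 3))   # accuracy per channel
        peak_ch = int(np.argmax(chan_mean))
        assert topo[peak_ch] > np.median(topo)
        cm = sl.channel_mean()
        assert cm.accuracy.shape == (3, 32, len(pseudo.times))

    def test_missing_channel_rejected(self, noise_pseudo):
        adj = {ch: {ch} for ch in list(noise_pseudo.layout.names)[:-1]}
        with pytest.raises(SchemeError):
            searchlight(noise_pseudo, adj, scheme("sex"))


class TestAdjacency:
    def test_delaunay_symmetric_with_neighbors(self):
        layout = biosemi64()
        adj = adjacency_from_layout(layout)
        assert set(adj) == set(layout.names)
        for ch, nbrs in adj.items():
            assert ch in nbrs and len(nbrs) >= 2
            for nb in nbrs:
                assert ch in adj[nb]

    def test_matrix_matches_map(self):
        layout = layout_for(16)
        adj = adjacency_from_layout(layout)
        m = adjacency_matrix(adj, list(layout.names))
        assert np.array_equal(m, m.T)
        assert m.diagonal().all()


class TestRoi:
    def test_six_region_partition_covers_montage(self):
        layout = biosemi64()
        rois = roi_map_from_layout(layout)
        assert set(rois) == set(fd.decode.ROI_LABELS)
        assert all(len(v) > 0 for v in rois.values())
        covered = set().union(*[set(v) for v in rois.values()])
        assert covered == set(layout.names)

    def test_roi_equal_to_full_when_all_channels(self, sex_effect_pseudo):
        names = list(sex_effect_pseudo.layout.names)
        out = roi_timecourse(sex_effect_pseudo, {"ALL": names}, scheme("sex"))
        full = loso_timecourse(sex_effect_pseudo, scheme("sex"))
        assert np.allclose(out["ALL"].accuracy, full.accuracy)

    def test_posterior_effect_prefers_posterior_roi(self, stim_set):
        layout = layout_for(16)
        topo = posterior_topography(layout, sharpness=6.0)
        eff = EffectSpec(attribute="sex", onset_ms=0, duration_ms=50,
                         amplitude=2.0, topography=topo)
        cfg = CohortConfig(n_participants=3, n_channels=16, tmin=0.0, tmax=0.05,
                           repetitions=6, effects=[eff], seed=17)
        epochs, _ = generate_cohort(cfg, stim_set)
        pseudo = fd.bin_average(epochs, 3, seed=17)
        y = layout.pos2d[:, 1]
        post = [layout.names[i] for i in np.argsort(y)[:5]]
        ant = [layout.names[i] for i in np.argsort(y)[-5:]]
        out = roi_timecourse(pseudo, {"POST": post, "ANT": ant}, scheme("sex"))
        assert out["POST"].participant_timecourse().mean() > \
            out["ANT"].participant_timecourse().mean()

    def test_empty_roi_rejected(self, noise_pseudo):
        with pytest.raises(SchemeError):
            roi_timecourse(noise_pseudo, {"LA": []}, scheme("sex"))
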