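"""Model RDMs, max cross-correlation, embeddings, partial rank correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

import facedecode as fd
from facedecode.montage import layout_for
from facedecode.preprocess import PseudoTrialSet
from facedecode.rsa import (ModelRDM, attribute_model_rdm, best_shift_euclidean,
                            embedding_rdm, max_crosscorr, max_crosscorr_rdm,
                            neural_rdm_series, rsa_correlate, vectorize_rdm)


class TestAttributeModels:
    def test_sex_model_block_structure(self, stim_set):
        m = attribute_model_rdm(stim_set, attribute="sex")
        assert m.matrix.shape == (32, 32)
        sexes = np.array([stim_set.attribute(s).sex for s in m.stimulus_order])
        same = sexes[:, None] == sexes[None, :]
        assert np.array_equal(m.matrix == 0, same)
        assert set(np.unique(m.matrix)) == {0.0, 1.0}

    def test_identity_model_rows_have_three_within_zeros(self, stim_set):
        m = attribute_model_rdm(stim_set, attribute="identity")
        off = m.matrix.copy()
        np.fill_diagonal(off, np.nan)
        zeros_per_row = np.nansum(off == 0, axis=1)
        assert (zeros_per_row == 3).all()      # 4 images per identity

    def test_expression_pair_model_16x16(self, stim_set):
        m = attribute_model_rdm(stim_set, expression_pair=("happy", "neutral"))
        assert m.matrix.shape == (16, 16)
        exprs = np.array([stim_set.attribute(s).expression for s in m.stimulus_order])
        assert set(exprs) == {"happy", "neutral"}
        assert np.array_equal(m.matrix == 1,
                              exprs[:, None] != exprs[None, :])

    def test_unknown_attribute_rejected(self, stim_set):
        with pytest.raises(ValueError):
            attribute_model_rdm(stim_set, attribute="age")


def _brute_force_max_xcorr(a, b, min_overlap_frac=0.5):
    """Exhaustive loop over every 2-D integer shift; Pearson r of overlap."""
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    h, w = a.shape
    min_n = max(3, int(np.ceil(min_overlap_frac * a.size)))
    best = -np.inf
    for dy in range(-(h - 1), h):
        for dx in range(-(w - 1), w):
            ya0, ya1 = max(0, dy), min(h, h + dy)
            xa0, xa1 = max(0, dx), min(w, w + dx)
            pa = az[ya0:ya1, xa0:xa1]
            pb = bz[ya0 - dy:ya1 - dy, xa0 - dx:xa1 - dx]
            if pa.size < min_n or pa.std() == 0 or pb.std() == 0:
                continue
            r = np.corrcoef(pa.ravel(), pb.ravel())[0, 1]
            best = max(best, r)
    return min(best, 1.0)


class TestMaxCrossCorrelation:
    def test_self_correlation_is_one(self, rng):
        img = rng.standard_normal((12, 12))
        assert max_crosscorr(img, img) == pytest.approx(1.0, abs=1e-10)
        rdm = max_crosscorr_rdm({"a": img, "b": img.copy()})
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_translation_invariance(self, rng):
        img = rng.standard_normal((16, 16))
        shifted = np.roll(np.roll(img, 3, axis=0), 2, axis=1)
        # rolled image equals a translation on the overlapping region
        assert max_crosscorr(img, shifted, min_overlap_frac=0.5) > 0.999

    def test_fft_matches_exhaustive_shift_oracle(self, rng):
        for _ in range(4):
            a, b = rng.standard_normal((2, 16, 16))
            fast = max_crosscorr(a, b)
            slow = _brute_force_max_xcorr(a, b)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            max_crosscorr(rng.standard_normal((8, 8)), rng.standard_normal((9, 8)))

    def test_euclidean_variant_zero_for_identical(self, rng):
        img = rng.standard_normal((10, 10))
        assert best_shift_euclidean(img, img) == pytest.approx(0.0, abs=1e-6)


class TestEmbeddingRdm:
    def test_hand_values(self):
        emb = {"a": np.array([0.0, 0.0]), "b": np.array([3.0, 4.0]),
               "c": np.array([0.0, 0.0])}
        m = embedding_rdm(emb, stimulus_order=["a", "b", "c"])
        assert m.matrix[0, 1] == pytest.approx(5.0)    # 3-4-5 triangle
        assert m.matrix[0, 2] == pytest.approx(0.0)    # duplicates

    def test_matches_elementwise_loop(self, rng):
        emb = {f"s{i}": rng.standard_normal(128) for i in range(32)}
        order = sorted(emb)
        m = embedding_rdm(emb, stimulus_order=order)
        for i in range(0, 32, 7):
            for j in range(0, 32, 5):
                expected = np.sqrt(np.sum((emb[order[i]] - emb[order[j]]) ** 2))
                assert m.matrix[i, j] == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            embedding_rdm({"a": np.zeros(4), "b": np.zeros(5)})


def _toy_rdm_series(matrices, order):
    """Wrap static matrices as a 1-participant RDM series."""
    vals = np.stack(matrices)[None]   # (1, T, n, n)
    return fd.rsa.RDMSeries(values=vals, stimulus_order=order,
                            times_ms=np.arange(len(matrices), dtype=float))


class TestRsaCorrelate:
    def _random_symmetric(self, rng, n):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, np.nan)
        return m

    def test_model_identical_to_neural_gives_rho_one(self, rng):
        m = self._random_symmetric(rng, 8)
        order = [f"s{i}" for i in range(8)]
        neural = _toy_rdm_series([m], order)
        model = ModelRDM(matrix=np.nan_to_num(m), stimulus_order=order)
        res = rsa_correlate(neural, model)
        assert res.rho[0, 0] == pytest.approx(1.0)
        assert res.z[0, 0] > 5  # Fisher z saturates near rho=1

    def test_self_covariate_removes_correlation(self, rng):
        m = self._random_symmetric(rng, 8)
        order = [f"s{i}" for i in range(8)]
        neural = _toy_rdm_series([m], order)
        model = ModelRDM(matrix=np.nan_to_num(m), stimulus_order=order)
        res = rsa_correlate(neural, model, covariates=[model])
        assert abs(res.rho[0, 0]) < 1e-8

    def test_partial_matches_recursive_formula(self, rng):
        """Single-covariate partial rank correlation equals the textbook
        recursion r_xy.z = (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2))."""
        order = [f"s{i}" for i in range(6)]
        x = self._random_symmetric(rng, 6)
        y = self._random_symmetric(rng, 6)
        z = self._random_symmetric(rng, 6)
        neural = _toy_rdm_series([x], order)
        model = ModelRDM(matrix=np.nan_to_num(y), stimulus_order=order)
        cov = ModelRDM(matrix=np.nan_to_num(z), stimulus_order=order)
        res = rsa_correlate(neural, model, covariates=[cov])
        vx, vy, vz = (vectorize_rdm(m) for m in (x, y, z))
        r_xy = spearmanr(vx, vy).statistic
        r_xz = spearmanr(vx, vz).statistic
        r_yz = spearmanr(vy, vz).statistic
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
        assert res.rho[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_ordering_mismatch_rejected(self, rng):
        order = [f"s{i}" for i in range(6)]
        neural = _toy_rdm_series([self._random_symmetric(rng, 6)], order)
        model = ModelRDM(matrix=np.zeros((6, 6)), stimulus_order=["x"] * 6)
        with pytest.raises(ValueError):
            rsa_correlate(neural, model)

    def test_pair_model_subsets_neural(self, stim_set, rng):
        order = stim_set.image_ids
        neural = _toy_rdm_series([self._random_symmetric(rng, 32)], order)
        pair = attribute_model_rdm(stim_set, expression_pair=("happy", "angry"))
        res = rsa_correlate(neural, pair)
        assert res.rho.shape == (1, 1)
        assert -1 <= res.rho[0, 0] <= 1

    def test_attenuation_logic(self, rng):
        """An image-correlated identity component is attenuated by the image
        covariate; an image-independent component is not."""
        order = [f"s{i}" for i in range(12)]
        ident = self._random_symmetric(rng, 12)
        image = 0.8 * ident + 0.2 * self._random_symmetric(rng, 12)   # collinear
        emo = self._random_symmetric(rng, 12)                          # independent
        neural_m = np.nansum(np.stack([0.5 * ident, 0.5 * image, 0.7 * emo]), axis=0)
        np.fill_diagonal(neural_m, np.nan)
        neural = _toy_rdm_series([neural_m], order)
        id_model = ModelRDM(matrix=np.nan_to_num(ident), stimulus_order=order)
        img_model = ModelRDM(matrix=np.nan_to_num(image), stimulus_order=order)
        emo_model = ModelRDM(matrix=np.nan_to_num(emo), stimulus_order=order)
        rho_id_plain = rsa_correlate(neural, id_model).rho[0, 0]
        rho_id_part = rsa_correlate(neural, id_model, covariates=[img_model]).rho[0, 0]
        rho_emo_plain = rsa_correlate(neural, emo_model).rho[0, 0]
        rho_emo_part = rsa_correlate(neural, emo_model, covariates=[img_model]).rho[0, 0]
        # the image covariate diminishes identity, but not emotion
        assert rho_id_part < rho_id_plain - 0.1
        assert rho_emo_part > rho_emo_plain - 0.05


def _patterned_pseudo(stim_set, patterns, n_participants=3, n_pseudo=2,
                      n_channels=8, n_times=3, noise=0.05, seed=0):
    """Hand-built pseudo-trial set: each image's response = pattern + noise."""
    rng = np.random.default_rng(seed)
    layout = layout_for(n_channels)
    data, meta = [], []
    for p in range(n_participants):
        rows, arrs = [], []
        for s in stim_set.stimuli:
            for b in range(n_pseudo):
                x = np.tile(patterns[s.image_id][:, None], (1, n_times))
                arrs.append(x + noise * rng.standard_normal((n_channels, n_times)))
                rows.append({"image_id": s.image_id, "identity": s.identity,
                             "sex": s.sex, "expression": s.expression, "bin": b,
                             "n_source_trials": 3})
        data.append(np.stack(arrs))
        meta.append(pd.DataFrame(rows))
    times = np.arange(n_times) / 200.0
    return PseudoTrialSet(data=data, metadata=meta, times=times, sfreq=200.0,
                          layout=layout, bin_size=3)


class TestNeuralRdm:
    def test_noise_only_cells_at_pairwise_chance(self, stim_set, rng):
        patterns = {s.image_id: np.zeros(8) for s in stim_set.stimuli}
        pseudo = _patterned_pseudo(stim_set, patterns, noise=1.0, seed=1)
        rdm = neural_rdm_series(pseudo)
        assert rdm.values.shape == (3, 3, 32, 32)
        sym = np.nan_to_num(rdm.values)
        assert np.allclose(sym, np.swapaxes(sym, 2, 3))
        assert np.isnan(rdm.values[..., np.arange(32), np.arange(32)]).all()
        cells = vectorize_rdm(rdm.mean()[0])
        assert abs(cells.mean() - 0.5) < 0.05

    def test_identical_patterns_confusable_distinct_patterns_separable(self, stim_set, rng):
        patterns = {s.image_id: rng.standard_normal(8) * 2 for s in stim_set.stimuli}
        ids = stim_set.image_ids
        patterns[ids[1]] = patterns[ids[0]].copy()    # two stimuli share a pattern
        pseudo = _patterned_pseudo(stim_set, patterns, n_pseudo=3, noise=0.3, seed=2)
        rdm = neural_rdm_series(pseudo, stimulus_order=ids)
        m = rdm.mean()[0]
        assert abs(m[0, 1] - 0.5) < 0.2               # shared pattern: chance
        others = np.concatenate([m[0, 2:], m[1, 2:]])
        assert others.mean() > 0.9                    # distinct patterns separate

    def test_missing_stimulus_rejected(self, stim_set):
        patterns = {s.image_id: np.zeros(8) for s in stim_set.stimuli}
        pseudo = _patterned_pseudo(stim_set, patterns, noise=1.0)
        pseudo.metadata[1] = pseudo.metadata[1].iloc[2:].reset_index(drop=True)
        pseudo.data[1] = pseudo.data[1][2:]
        with pytest.raises(fd.decode.SchemeError, match="missing stimulus"):
            neural_rdm_series(pseudo)
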