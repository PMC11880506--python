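"""Canned evaluation protocols: calibration and parameter recovery.

These functions bundle the study-shaped simulations used to validate the
pipeline end to end:

* :func:`noise_calibration` — leave-one-participant-out decoding of a
  cohort with no class-dependent signal must sit at the scheme chance
  levels (identity 0.125, sex 0.5, emotion 0.25);
* :func:`fwe_calibration` — the cluster permutation test's family-wise
  false-positive rate over many null cohorts must match its alpha;
* :func:`onset_recovery` — cohorts with an effect planted at a known
  latency must yield Bayes-factor onsets at that latency, and staggered
  latencies across attributes must come back in the planted order.  One
  cohort is simulated per attribute: attribute hierarchies overlap (any
  pattern that separates the sexes also separates identities across sex),
  so effects planted jointly would confound threshold-crossing onsets;
* :func:`attenuation_recovery` — when the neural dissimilarity structure
  contains an image-driven identity component, partialling out the
  image-similarity model must attenuate the identity correlation while
  leaving an image-independent expression effect intact.

The reduced problem sizes used here (6-10 participants, 16-64 channels,
50-80 timepoints) keep each protocol in the minutes range on one CPU while
preserving the full analysis logic.
"""

from __future__ import annotations

import numpy as np

from . import decode, rsa, stats, synth
from ._seeding import int_seed, rng_for
from .design import build_stimulus_set
from .preprocess import bin_average
from .synth import CohortConfig, EffectSpec


def noise_calibration(seed: int, n_participants: int = 6, n_channels: int = 64,
                      tmin: float = -0.05, tmax: float = 0.2,
                      repetitions: int = 12,
                      targets: tuple[str, ...] = ("identity", "sex", "emotion"),
                      ) -> dict[str, dict]:
    """Time- and fold-averaged LOSO accuracy on a signal-free cohort.

    Returns, per scheme, the grand-mean accuracy, the scheme's chance level,
    and the number of (participant, fold, time) accuracy values averaged.
    """
    stim = build_stimulus_set()
    cfg = CohortConfig(n_participants=n_participants, n_channels=n_channels,
                       tmin=tmin, tmax=tmax, repetitions=repetitions,
                       seed=int_seed(seed, "noise-cal"))
    epochs, _ = synth.generate_cohort(cfg, stim)
    pseudo = bin_average(epochs, bin_size=3, seed=int_seed(seed, "noise-cal-bins"))
    out = {}
    for target in targets:
        res = decode.loso_timecourse(pseudo, decode.scheme(target))
        acc = res.accuracy
        out[target] = {
            "mean_accuracy": float(acc.mean()),
            "chance": res.chance,
            "n_values": int(acc.size),
            "participant_means": acc.mean(axis=(1, 2)).tolist(),
        }
    return out


def fwe_calibration(seed: int, n_sims: int = 500, n_participants: int = 8,
                    n_times: int = 20, alpha: float = 0.05,
                    noise_ar: float = 0.6) -> dict:
    """Family-wise false-positive rate of the cluster permutation test.

    Simulates ``n_sims`` null cohorts of temporally autocorrelated
    participant series centered on chance, runs the two-sided cluster test
    (exhaustive sign-flip null at this cohort size), and reports the
    fraction of simulations with any cluster at p <= alpha.

    The exhaustive null of n participants holds 2^n sign vectors but only
    2^(n-1) distinct max-|mass| values (a global flip preserves every |t|),
    so the achievable family-wise rate at alpha = 0.05 is floor(alpha *
    2^(n-1)) / 2^(n-1); n = 8 gives 6/128 ~ 0.047, close enough to nominal
    to calibrate against, whereas n = 6 caps at 1/32 ~ 0.031.
    """
    rng = rng_for(seed, "fwe")
    times_ms = np.arange(n_times) * 5.0
    min_pvals = []
    for _ in range(n_sims):
        x = rng.standard_normal((n_participants, n_times))
        for t in range(1, n_times):   # AR(1) temporal correlation
            x[:, t] = noise_ar * x[:, t - 1] + np.sqrt(1 - noise_ar ** 2) * x[:, t]
        bundle = stats.SeriesBundle(values=0.5 + 0.05 * x, chance=0.5,
                                    times_ms=times_ms)
        res = stats.cluster_permutation(bundle, n_perm=2 ** n_participants)
        ps = [c.p for c in res.clusters]
        min_pvals.append(min(ps) if ps else 1.0)
    min_pvals = np.asarray(min_pvals)
    return {"fwe_rate": float((min_pvals <= alpha).mean()), "alpha": alpha,
            "n_sims": n_sims, "min_pvals": min_pvals.tolist()}


#: Attribute -> decoding scheme used to recover its planted effect.
_RECOVERY_SCHEMES = {"sex": "sex", "identity": "identity", "emotion": "emotion"}


def onset_recovery(seed: int, onsets_ms: dict[str, float] | None = None,
                   duration_ms: float = 150.0, amplitude: float = 1.5,
                   n_participants: int = 8, n_channels: int = 16,
                   tmin: float = -0.1, tmax: float = 0.3,
                   repetitions: int = 6, smoothing_ms: float = 35.0,
                   bf_threshold: float = 10.0) -> dict[str, dict]:
    """Plant one effect per attribute at a known onset and recover it.

    For each attribute a separate cohort is generated with a single shared
    effect; the matching decoding scheme is run, accuracies are smoothed
    with the standard 35 ms window, and the onset is the first timepoint
    with an interval-null Bayes factor above threshold.
    """
    if onsets_ms is None:
        onsets_ms = {"sex": 50.0, "identity": 90.0, "emotion": 130.0}
    stim = build_stimulus_set()
    out = {}
    for attr, onset in onsets_ms.items():
        eff = EffectSpec(attribute="expression" if attr == "emotion" else attr,
                         onset_ms=onset, duration_ms=duration_ms,
                         amplitude=amplitude)
        cfg = CohortConfig(n_participants=n_participants, n_channels=n_channels,
                           tmin=tmin, tmax=tmax, repetitions=repetitions,
                           effects=[eff], seed=int_seed(seed, "recovery", attr))
        epochs, _ = synth.generate_cohort(cfg, stim)
        pseudo = bin_average(epochs, bin_size=3,
                             seed=int_seed(seed, "recovery-bins", attr))
        res = decode.loso_timecourse(pseudo, decode.scheme(_RECOVERY_SCHEMES[attr]))
        bundle = stats.SeriesBundle.from_decoding(res).smoothed(smoothing_ms)
        bf = stats.bayes_factor_series(bundle, threshold=bf_threshold)
        # debounce with one smoothing window: LOSO folds share training data,
        # so at small n momentary t inflation can push isolated samples past
        # threshold; a real effect smoothed over 35 ms spans >= 7 samples
        min_run = max(1, int(round(smoothing_ms / 1000.0 * pseudo.sfreq)))
        op = stats.onset_peak(bf, min_run=min_run)
        out[attr] = {"planted_onset_ms": float(onset), **op,
                     "max_accuracy": float(bundle.values.mean(axis=0).max())}
    return out


def attenuation_recovery(seed: int, alpha_identity: float = 0.5,
                         beta_image: float = 1.0, gamma_expression: float = 0.8,
                         noise_sd: float = 0.3, n_times: int = 5) -> dict:
    """Partial-correlation control of image properties, on planted RDMs.

    Builds a neural RDM series as alpha * identity-model + beta * image-RDM
    + gamma * expression-model + noise, where the image RDM comes from
    synthetic rasters with identity structure (so it is collinear with the
    identity model but carries no expression structure).  Returns the plain
    and image-partialled correlations for the identity and expression
    models; the partial must attenuate identity but not expression.
    """
    stim = build_stimulus_set()
    order = stim.image_ids
    rasters = synth.generate_images(
        stim, image_size=(16, 16),
        structure_weights={"identity": 2.0, "sex": 0.0, "expression": 0.0},
        noise_weight=0.7, seed=int_seed(seed, "atten-img"))
    image_model = rsa.max_crosscorr_rdm(rasters, stimulus_order=order)
    id_model = rsa.attribute_model_rdm(stim, attribute="identity")
    expr_model = rsa.attribute_model_rdm(stim, attribute="expression")

    img = image_model.matrix / image_model.matrix.max()
    rng = rng_for(seed, "atten-noise")
    mats = []
    for _ in range(n_times):
        m = (alpha_identity * id_model.matrix + beta_image * img
             + gamma_expression * expr_model.matrix)
        e = rng.standard_normal(m.shape) * noise_sd
        m = m + (e + e.T) / 2
        np.fill_diagonal(m, np.nan)
        mats.append(m)
    neural = rsa.RDMSeries(values=np.stack(mats)[None],
                           stimulus_order=order,
                           times_ms=np.arange(n_times, dtype=float))

    def mean_rho(model, covs):
        return float(np.mean(rsa.rsa_correlate(neural, model, covariates=covs).rho))

    return {
        "identity_plain": mean_rho(id_model, []),
        "identity_partial_image": mean_rho(id_model, [image_model]),
        "expression_plain": mean_rho(expr_model, []),
        "expression_partial_image": mean_rho(expr_model, [image_model]),
    }
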