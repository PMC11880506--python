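"""Representational similarity analysis with partial rank correlations.

Neural representational dissimilarity matrices (RDMs) are built per
timepoint by cross-participant pairwise decoding of all 496 unordered
stimulus pairs: the cell for a pair holds the leave-one-participant-out
2-class accuracy, so 0.5 means indistinguishable patterns.  These time
courses are compared with model RDMs — binary attribute structure (0 within
class, 1 across), maximum image cross-correlation, and face-embedding
Euclidean distance — via Spearman correlations on the lower triangle,
Fisher-transformed; covariate RDMs can be partialled out by rank
residualization to control for low-level image properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.signal import fftconvolve
from scipy.stats import rankdata

from .decode import ClassifierConfig, SchemeError, fit_predict_timepoint
from .design import EXPRESSIONS, StimulusSet
from .preprocess import PseudoTrialSet


@dataclass
class RDMSeries:
    """Time-resolved stimulus dissimilarity, fold-resolved by participant.

    values has shape (n_participants, n_times, n_stimuli, n_stimuli) where
    the participant axis indexes the held-out fold; each matrix is symmetric
    with a masked (NaN) diagonal and cells in [0, 1] (pairwise decoding
    accuracy).  ``mean()`` collapses folds for display.
    """

    values: np.ndarray
    stimulus_order: list[str]
    times_ms: np.ndarray

    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]


@dataclass
class ModelRDM:
    """A static predictor dissimilarity matrix over stimuli."""

    matrix: np.ndarray
    stimulus_order: list[str]
    kind: str = "attribute-binary"
    name: str = ""

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.stimulus_order):
            raise ValueError("matrix must be square over the stimulus order")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("model RDM must be symmetric")


@dataclass
class RSAResult:
    """Per-timepoint model correlations.

    rho has shape (n_participants, n_times) for fold-resolved neural input
    (each row is one held-out fold's RDM series) and (n_times,) otherwise;
    z is the Fisher transform atanh(rho).
    """

    rho: np.ndarray
    z: np.ndarray
    times_ms: np.ndarray
    model_name: str = ""
    covariates: list[str] = field(default_factory=list)


def _tri_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(n, k=-1)


def vectorize_rdm(matrix: np.ndarray) -> np.ndarray:
    """Lower triangle (diagonal excluded) as a flat vector."""
    i, j = _tri_indices(matrix.shape[0])
    return matrix[i, j]


# ---------------------------------------------------------------------------
# neural RDMs

def neural_rdm_series(pseudo: PseudoTrialSet, stimulus_order: list[str] | None = None,
                      config: ClassifierConfig = ClassifierConfig()) -> RDMSeries:
    """Pairwise LOSO decoding accuracy for every stimulus pair and timepoint.

    For each unordered pair a 2-class linear discriminant is trained on
    every participant but one and tested on the held-out participant's
    pseudo-trials of those two stimuli; the accuracy fills the pair's cell
    in that fold's RDM.  Requires every stimulus present for every
    participant.
    """
    if pseudo.n_participants < 3:
        raise SchemeError("need at least 3 participants")
    if stimulus_order is None:
        stimulus_order = sorted(pseudo.metadata[0]["image_id"].unique())
    n_stim = len(stimulus_order)
    idx_per_p = []
    for p, md in enumerate(pseudo.metadata):
        d = {}
        for s in stimulus_order:
            rows = np.flatnonzero((md["image_id"] == s).to_numpy())
            if rows.size == 0:
                raise SchemeError(f"participant {p} is missing stimulus {s!r}")
            d[s] = rows
        idx_per_p.append(d)

    n_p, n_t = pseudo.n_participants, len(pseudo.times)
    values = np.full((n_p, n_t, n_stim, n_stim), np.nan)
    for a, b in combinations(range(n_stim), 2):
        sa, sb = stimulus_order[a], stimulus_order[b]
        for p_test in range(n_p):
            xs, ys = [], []
            for p in range(n_p):
                if p == p_test:
                    continue
                ia, ib = idx_per_p[p][sa], idx_per_p[p][sb]
                xs.append(pseudo.data[p][ia]); ys.append(np.zeros(len(ia), int))
                xs.append(pseudo.data[p][ib]); ys.append(np.ones(len(ib), int))
            x_train = np.concatenate(xs); y_train = np.concatenate(ys)
            ia, ib = idx_per_p[p_test][sa], idx_per_p[p_test][sb]
            x_test = np.concatenate([pseudo.data[p_test][ia], pseudo.data[p_test][ib]])
            y_test = np.concatenate([np.zeros(len(ia), int), np.ones(len(ib), int)])
            for t in range(n_t):
                acc = fit_predict_timepoint(x_train[:, :, t], y_train,
                                            x_test[:, :, t], y_test, config)
                values[p_test, t, a, b] = acc
                values[p_test, t, b, a] = acc
    return RDMSeries(values=values, stimulus_order=list(stimulus_order),
                     times_ms=pseudo.times_ms)


# ---------------------------------------------------------------------------
# model RDMs

def attribute_model_rdm(stimulus_set: StimulusSet, attribute: str | None = None,
                        expression_pair: tuple[str, str] | None = None) -> ModelRDM:
    """Binary model RDM: 0 within class, 1 across.

    Either an attribute over all 32 stimuli (identity / sex / expression) or
    an expression pair, which restricts the matrix to the 16 stimuli of the
    two expressions and codes same-vs-different expression.
    """
    if (attribute is None) == (expression_pair is None):
        raise ValueError("give exactly one of attribute or expression_pair")
    if expression_pair is not None:
        bad = set(expression_pair) - set(EXPRESSIONS)
        if bad:
            raise ValueError(f"unknown expressions: {bad}")
        stims = [s for s in stimulus_set.stimuli if s.expression in expression_pair]
        order = [s.image_id for s in stims]
        labels = [s.expression for s in stims]
        name = f"pair:{expression_pair[0]}-{expression_pair[1]}"
    else:
        if attribute not in ("identity", "sex", "expression"):
            raise ValueError(f"unknown attribute {attribute!r}")
        order = stimulus_set.image_ids
        labels = [getattr(stimulus_set.attribute(s), attribute) for s in order]
        name = attribute
    lab = np.asarray(labels)
    m = (lab[:, None] != lab[None, :]).astype(float)
    return ModelRDM(matrix=m, stimulus_order=order, kind="attribute-binary", name=name)


def _overlap_stats(a: np.ndarray, b: np.ndarray):
    """FFT cross-correlation sums needed for per-overlap Pearson r."""
    ones_a, ones_b = np.ones_like(a), np.ones_like(b)
    flip = (slice(None, None, -1), slice(None, None, -1))
    conv = lambda x, y: fftconvolve(x, y[flip], mode="full")
    n = conv(ones_a, ones_b)
    return {
        "n": n,
        "sa": conv(a, ones_b), "sb": conv(ones_a, b),
        "saa": conv(a * a, ones_b), "sbb": conv(ones_a, b * b),
        "sab": conv(a, b),
    }


def max_crosscorr(a: np.ndarray, b: np.ndarray, min_overlap_frac: float = 0.5,
                  ) -> float:
    """Maximum over all integer 2-D translations of the overlap Pearson r.

    Each image is z-scored; for every relative shift the correlation of the
    overlapping region is computed (via FFT sum tables), and the maximum
    over shifts with at least ``min_overlap_frac`` of the pixels overlapping
    is returned — the best correlation achievable had the images been
    optimally co-registered.
    """
    if a.shape != b.shape:
        raise ValueError(f"raster shapes differ: {a.shape} vs {b.shape}")
    az = (a - a.mean()) / (a.std() + 1e-300)
    bz = (b - b.mean()) / (b.std() + 1e-300)
    s = _overlap_stats(az, bz)
    n = np.round(s["n"]).astype(int)
    min_n = max(3, int(np.ceil(min_overlap_frac * a.size)))
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s["sab"] - s["sa"] * s["sb"] / n
        va = s["saa"] - s["sa"] ** 2 / n
        vb = s["sbb"] - s["sb"] ** 2 / n
        r = cov / np.sqrt(np.clip(va, 0, None) * np.clip(vb, 0, None))
    r = np.where((n >= min_n) & np.isfinite(r), r, -np.inf)
    return float(np.clip(r.max(), -1.0, 1.0))


def best_shift_euclidean(a: np.ndarray, b: np.ndarray,
                         min_overlap_frac: float = 0.5) -> float:
    """Per-pixel Euclidean distance at the correlation-maximizing shift.

    A literal distance-at-best-registration variant of the image-similarity
    metric, provided for comparison with the 1 - max-correlation default.
    """
    if a.shape != b.shape:
        raise ValueError("raster shapes differ")
    az = (a - a.mean()) / (a.std() + 1e-300)
    bz = (b - b.mean()) / (b.std() + 1e-300)
    s = _overlap_stats(az, bz)
    n = np.round(s["n"]).astype(int)
    min_n = max(3, int(np.ceil(min_overlap_frac * a.size)))
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s["sab"] - s["sa"] * s["sb"] / n
        va = s["saa"] - s["sa"] ** 2 / n
        vb = s["sbb"] - s["sb"] ** 2 / n
        r = cov / np.sqrt(np.clip(va, 0, None) * np.clip(vb, 0, None))
    r = np.where((n >= min_n) & np.isfinite(r), r, -np.inf)
    k = np.unravel_index(np.argmax(r), r.shape)
    sq = s["saa"][k] + s["sbb"][k] - 2 * s["sab"][k]
    return float(np.sqrt(max(sq, 0.0) / n[k]))


def max_crosscorr_rdm(rasters: dict[str, np.ndarray],
                      stimulus_order: list[str] | None = None,
                      min_overlap_frac: float = 0.5,
                      metric: str = "one-minus-corr") -> ModelRDM:
    """Low-level image-similarity RDM from maximum cross-correlation.

    Default dissimilarity is ``1 - max cross-correlation``; the
    ``euclidean-at-best-shift`` metric is the literal-distance variant.
    """
    order = stimulus_order or sorted(rasters)
    shapes = {rasters[k].shape for k in order}
    if len(shapes) != 1:
        raise ValueError(f"rasters must share one shape, got {shapes}")
    n = len(order)
    m = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        if metric == "one-minus-corr":
            d = 1.0 - max_crosscorr(rasters[order[i]], rasters[order[j]],
                                    min_overlap_frac)
        elif metric == "euclidean-at-best-shift":
            d = best_shift_euclidean(rasters[order[i]], rasters[order[j]],
                                     min_overlap_frac)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        m[i, j] = m[j, i] = d
    return ModelRDM(matrix=m, stimulus_order=order, kind="max-crosscorr",
                    name=f"max-crosscorr[{metric}]")


def embedding_rdm(embeddings: dict[str, np.ndarray],
                  stimulus_order: list[str] | None = None) -> ModelRDM:
    """Pairwise Euclidean distances between face-descriptor vectors."""
    order = stimulus_order or sorted(embeddings)
    vecs = [np.asarray(embeddings[k], float).ravel() for k in order]
    lengths = {v.shape[0] for v in vecs}
    if len(lengths) != 1:
        raise ValueError(f"embedding lengths differ: {lengths}")
    m = squareform(pdist(np.stack(vecs), metric="euclidean"))
    return ModelRDM(matrix=m, stimulus_order=order, kind="embedding-distance",
                    name="embedding")


# ---------------------------------------------------------------------------
# correlation

def _partial_spearman(x: np.ndarray, y: np.ndarray,
                      covs: list[np.ndarray]) -> float:
    """Spearman correlation of x and y, covariates regressed from the ranks.

    All vectors are rank-transformed (average ranks for ties); covariate
    ranks plus an intercept are regressed out of both x and y ranks and the
    residuals are Pearson-correlated.  Without covariates this is plain
    Spearman rho.
    """
    rx, ry = rankdata(x), rankdata(y)
    ss_x = ((rx - rx.mean()) ** 2).sum()
    ss_y = ((ry - ry.mean()) ** 2).sum()
    if covs:
        design = np.column_stack([np.ones(len(rx))] + [rankdata(c) for c in covs])
        rx = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
        ry = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    else:
        rx = rx - rx.mean()
        ry = ry - ry.mean()
    # residuals that are numerically zero (a covariate explains the vector
    # entirely, e.g. self-residualization) carry no correlation
    if (ss_x > 0 and (rx ** 2).sum() < 1e-12 * ss_x) or \
            (ss_y > 0 and (ry ** 2).sum() < 1e-12 * ss_y):
        return 0.0
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))


def rsa_correlate(neural: RDMSeries, model: ModelRDM,
                  covariates: list[ModelRDM] | None = None) -> RSAResult:
    """Time-resolved (partial) Spearman correlation of neural and model RDMs.

    The neural series is fold-resolved: correlations are computed per
    held-out participant and timepoint on the lower-triangle vectors, with
    covariate RDM ranks regressed out of both sides when given, then
    Fisher-transformed.  Stimulus orderings must match exactly — the model
    (and covariates) may cover a subset of the neural stimuli (e.g. an
    expression pair), in which case the neural RDM is restricted to that
    subset in the model's order.
    """
    covariates = covariates or []
    if not set(model.stimulus_order) <= set(neural.stimulus_order):
        raise ValueError("model stimuli are not a subset of the neural RDM's")
    for cov in covariates:
        if cov.stimulus_order != model.stimulus_order:
            raise ValueError(
                f"covariate {cov.name!r} ordering does not match the model's")
    sel = [neural.stimulus_order.index(s) for s in model.stimulus_order]
    if sel == list(range(len(neural.stimulus_order))):
        sub = neural.values
    else:
        sub = neural.values[:, :, sel][:, :, :, sel]
    mv = vectorize_rdm(model.matrix)
    cvs = [vectorize_rdm(c.matrix) for c in covariates]
    n_p, n_t = sub.shape[:2]
    rho = np.empty((n_p, n_t))
    i, j = _tri_indices(len(sel))
    for p in range(n_p):
        for t in range(n_t):
            rho[p, t] = _partial_spearman(sub[p, t][i, j], mv, cvs)
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
    return RSAResult(rho=rho, z=z, times_ms=neural.times_ms,
                     model_name=model.name,
                     covariates=[c.name for c in covariates])
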