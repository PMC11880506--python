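"""Leave-one-participant-out (LOSO) linear-discriminant decoding.

Classifiers are trained on every participant but one and tested on the
held-out participant, so above-chance accuracy implies stimulus information
carried by neural patterns *shared* across observers.  Besides the held-out
participant, each fold also holds out a stimulus condition:

* identity (8-class): train on three expressions, test on the held-out
  participant's held-out expression (4 folds per participant);
* sex (2-class), emotion (4-class) and emotion pairs (2-class): train on six
  identities, three per sex, test on a held-out identity.  Holding out one
  identity leaves 3 of its sex and 4 of the other, so one opposite-sex
  identity is additionally excluded to keep training sex-balanced at 3/3;
  the excluded identity rotates over the 4 possibilities and all rotations
  are averaged (8 x 4 = 32 folds per participant).

Chance levels are 1/n_classes: identity 0.125, sex 0.5, emotion 0.25,
expression pairs 0.5.  Schemes can be run on all electrodes, per region of
interest, or as a spatio-temporal searchlight over each channel's
neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ._fast_lda import FastShrinkageLDA
from .design import EXPRESSIONS
from .montage import ChannelLayout
from .preprocess import PseudoTrialSet

ROI_LABELS = ("LA", "RA", "LC", "RC", "LP", "RP")


class SchemeError(ValueError):
    """Raised when a decoding scheme and the trial metadata disagree."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Linear discriminant settings.

    The default lsqr solver with Ledoit-Wolf covariance shrinkage stays
    well-conditioned when channels rival trials per class (the searchlight
    regime); the plain SVD solver is available for comparison.  The lsqr
    route uses an in-package implementation with the same decision rule as
    scikit-learn's (equivalence is asserted in the test suite) but without
    per-call validation overhead; ``use_sklearn`` forces the scikit-learn
    estimator.
    """

    solver: str = "lsqr"
    shrinkage: str | float | None = "auto"
    use_sklearn: bool = False

    def make(self):
        if self.solver == "svd":
            return LinearDiscriminantAnalysis(solver="svd")
        if self.solver != "lsqr":
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.use_sklearn:
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=self.shrinkage)
        return FastShrinkageLDA(shrinkage=self.shrinkage)


@dataclass(frozen=True)
class SchemeSpec:
    """A decoding target plus optional cross-classification flavor."""

    target: str                       # identity | sex | emotion | emotion_pair
    pair: tuple[str, str] | None = None
    generalization: str | None = None

    def __post_init__(self) -> None:
        if self.target not in ("identity", "sex", "emotion", "emotion_pair"):
            raise SchemeError(f"unknown target {self.target!r}")
        if self.target == "emotion_pair":
            if self.pair is None or len(self.pair) != 2 or \
                    not set(self.pair) <= set(EXPRESSIONS):
                raise SchemeError("emotion_pair needs a valid expression pair")
        elif self.pair is not None:
            raise SchemeError("pair is only valid for emotion_pair")

    @property
    def n_classes(self) -> int:
        return {"identity": 8, "sex": 2, "emotion": 4, "emotion_pair": 2}[self.target]

    @property
    def chance(self) -> float:
        return 1.0 / self.n_classes

    @property
    def label_column(self) -> str:
        return {"identity": "identity", "sex": "sex",
                "emotion": "expression", "emotion_pair": "expression"}[self.target]


def scheme(target: str, pair: tuple[str, str] | None = None) -> SchemeSpec:
    return SchemeSpec(target=target, pair=pair)


@dataclass
class DecodingResult:
    """Accuracy time courses per participant and fold.

    accuracy has shape (n_participants, n_folds, n_times) or, for the
    searchlight, (n_participants, n_folds, n_channels, n_times).  folds
    lists one descriptor dict per fold (held-out condition, excluded
    identity, train participants).
    """

    accuracy: np.ndarray
    scheme: SchemeSpec
    chance: float
    times_ms: np.ndarray
    folds: list[dict]
    ch_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = self.accuracy
        if a.size and (a.min() < 0 or a.max() > 1):
            raise ValueError("accuracies must lie in [0, 1]")

    def participant_timecourse(self) -> np.ndarray:
        """Fold-averaged accuracy, shape (n_participants, n_times)."""
        return self.accuracy.mean(axis=1)

    def channel_mean(self) -> "DecodingResult":
        """Searchlight accuracies averaged over channels (onset estimation)."""
        if self.accuracy.ndim != 4:
            raise ValueError("channel_mean requires a searchlight result")
        return DecodingResult(accuracy=self.accuracy.mean(axis=2),
                              scheme=self.scheme, chance=self.chance,
                              times_ms=self.times_ms, folds=self.folds,
                              meta=dict(self.meta, channel_mean=True))

    def summary_frame(self) -> pd.DataFrame:
        """Tidy CSV-ready frame of the participant-mean time course."""
        pt = self.participant_timecourse()
        return pd.DataFrame({
            "time_ms": self.times_ms,
            "mean_accuracy": pt.mean(axis=0),
            "sem": pt.std(axis=0, ddof=1) / np.sqrt(pt.shape[0]) if pt.shape[0] > 1 else np.nan,
            "chance": self.chance,
        })


def fit_predict_timepoint(train_patterns: np.ndarray, train_labels,
                          test_patterns: np.ndarray, test_labels,
                          config: ClassifierConfig = ClassifierConfig()) -> float:
    """Train a linear discriminant and return the fraction correct on test."""
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    classes = set(train_labels)
    if len(classes) < 2:
        raise SchemeError("training set must contain at least 2 classes")
    missing = set(test_labels) - classes
    if missing:
        raise SchemeError(f"classes absent from training: {sorted(missing)}")
    if train_patterns.shape[1] != test_patterns.shape[1]:
        raise SchemeError("train/test pattern dimensions differ")
    clf = config.make()
    clf.fit(train_patterns, train_labels)
    return float(np.mean(clf.predict(test_patterns) == test_labels))


# ---------------------------------------------------------------------------
# fold construction

def _identities_by_sex(md: pd.DataFrame) -> dict[str, list[str]]:
    tab = md.drop_duplicates("identity")[["identity", "sex"]]
    return {sex: sorted(tab.loc[tab["sex"] == sex, "identity"])
            for sex in ("male", "female")}


def _scheme_folds(scheme: SchemeSpec, md: pd.DataFrame) -> list[dict]:
    """Condition folds for one participant's metadata (participant-agnostic)."""
    if scheme.target == "identity":
        return [{"held_out_expression": e} for e in EXPRESSIONS]
    by_sex = _identities_by_sex(md)
    if any(len(v) != 4 for v in by_sex.values()):
        raise SchemeError("sex/emotion schemes need 4 identities per sex")
    folds = []
    for sex in ("male", "female"):
        other = "female" if sex == "male" else "male"
        for test_id in by_sex[sex]:
            for excl in by_sex[other]:
                folds.append({"held_out_identity": test_id,
                              "excluded_identity": excl})
    return folds


def _fold_masks(scheme: SchemeSpec, md: pd.DataFrame, fold: dict,
                ) -> tuple[np.ndarray, np.ndarray]:
    """(train_mask, test_mask) over one participant's pseudo-trials."""
    base = np.ones(len(md), bool)
    if scheme.target == "emotion_pair":
        base &= md["expression"].isin(scheme.pair).to_numpy()
    if not fold:
        # cross-classification with no condition holdout: the train/test
        # restriction comes entirely from the condition masks
        return base.copy(), base.copy()
    if scheme.target == "identity":
        expr = fold["held_out_expression"]
        train = base & (md["expression"] != expr).to_numpy()
        test = base & (md["expression"] == expr).to_numpy()
    else:
        tid, excl = fold["held_out_identity"], fold["excluded_identity"]
        train = base & (~md["identity"].isin([tid, excl])).to_numpy()
        test = base & (md["identity"] == tid).to_numpy()
    return train, test


def _decode_fold(pseudo: PseudoTrialSet, scheme: SchemeSpec, fold: dict,
                 test_participant: int, config: ClassifierConfig,
                 channels: np.ndarray | None,
                 train_condition: np.ndarray | None = None,
                 test_condition: np.ndarray | None = None) -> np.ndarray:
    """Per-timepoint accuracies for one (participant, condition) fold.

    ``train_condition``/``test_condition`` optionally restrict trials (for
    cross-classification); they are boolean masks evaluated per participant
    via the metadata (passed as per-participant arrays by the caller).
    """
    col = scheme.label_column
    xs, ys = [], []
    for p in range(pseudo.n_participants):
        if p == test_participant:
            continue
        md = pseudo.metadata[p]
        train_mask, _ = _fold_masks(scheme, md, fold)
        if train_condition is not None:
            train_mask = train_mask & train_condition[p]
        xs.append(pseudo.data[p][train_mask])
        ys.append(md.loc[train_mask, col].to_numpy())
    x_train = np.concatenate(xs)
    y_train = np.concatenate(ys)

    md_t = pseudo.metadata[test_participant]
    _, test_mask = _fold_masks(scheme, md_t, fold)
    if test_condition is not None:
        test_mask = test_mask & test_condition[test_participant]
    if not test_mask.any():
        raise SchemeError("empty test set for fold; scheme/metadata mismatch")
    x_test = pseudo.data[test_participant][test_mask]
    y_test = md_t.loc[test_mask, col].to_numpy()

    if channels is not None:
        x_train = x_train[:, channels]
        x_test = x_test[:, channels]
    n_times = x_train.shape[-1]
    acc = np.empty(n_times)
    for t in range(n_times):
        acc[t] = fit_predict_timepoint(x_train[:, :, t], y_train,
                                       x_test[:, :, t], y_test, config)
    return acc


def loso_timecourse(pseudo: PseudoTrialSet, scheme: SchemeSpec,
                    config: ClassifierConfig = ClassifierConfig(),
                    channels: list[int] | np.ndarray | None = None,
                    ) -> DecodingResult:
    """Time-resolved LOSO decoding in the given scheme.

    Returns per-participant, per-fold accuracy time courses; ``channels``
    optionally restricts features to a channel subset (used by ROI and
    searchlight decoding).
    """
    if pseudo.n_participants < 3:
        raise SchemeError("LOSO decoding needs at least 3 participants")
    ch = None if channels is None else np.asarray(channels, int)
    folds = _scheme_folds(scheme, pseudo.metadata[0])
    n_p, n_t = pseudo.n_participants, len(pseudo.times)
    acc = np.empty((n_p, len(folds), n_t))
    fold_records = []
    for fi, fold in enumerate(folds):
        for p in range(n_p):
            acc[p, fi] = _decode_fold(pseudo, scheme, fold, p, config, ch)
        fold_records.append(dict(fold))
    return DecodingResult(accuracy=acc, scheme=scheme, chance=scheme.chance,
                          times_ms=pseudo.times_ms, folds=fold_records,
                          meta={"channels": None if ch is None else ch.tolist()})


def _condition_masks(pseudo: PseudoTrialSet, condition) -> list[np.ndarray]:
    """Resolve a condition spec into per-participant boolean trial masks."""
    masks = []
    for md in pseudo.metadata:
        if isinstance(condition, str):
            m = (md["expression"] == condition).to_numpy()
        elif callable(condition):
            m = np.asarray(condition(md), bool)
        else:
            m = np.asarray(condition, bool)
        if not m.any():
            raise SchemeError("condition selects no trials")
        masks.append(m)
    return masks


def cross_classify_conditions(pseudo: PseudoTrialSet, scheme: SchemeSpec,
                              condition_a, condition_b,
                              config: ClassifierConfig = ClassifierConfig(),
                              channels=None) -> DecodingResult:
    """Bidirectional cross-classification between two trial conditions.

    Trains on condition A of the training participants and tests on
    condition B of the held-out participant, then the reverse; the two
    direction accuracies are averaged within participant.  For the identity
    scheme the condition split replaces the held-out-expression fold (the
    conditions are typically expressions, e.g. neutral vs angry).
    """
    ma = _condition_masks(pseudo, condition_a)
    mb = _condition_masks(pseudo, condition_b)
    ch = None if channels is None else np.asarray(channels, int)
    if scheme.target == "identity":
        folds = [{}]
    else:
        folds = _scheme_folds(scheme, pseudo.metadata[0])
    n_p, n_t = pseudo.n_participants, len(pseudo.times)
    acc = np.empty((n_p, len(folds), n_t))
    for fi, fold in enumerate(folds):
        for p in range(n_p):
            fwd = _decode_fold(pseudo, scheme, fold, p, config, ch,
                               train_condition=ma, test_condition=mb)
            rev = _decode_fold(pseudo, scheme, fold, p, config, ch,
                               train_condition=mb, test_condition=ma)
            acc[p, fi] = 0.5 * (fwd + rev)
    return DecodingResult(accuracy=acc, scheme=scheme, chance=scheme.chance,
                          times_ms=pseudo.times_ms, folds=[dict(f) for f in folds],
                          meta={"cross_classification": True})


# ---------------------------------------------------------------------------
# channel neighborhoods, searchlight, regions of interest

def adjacency_from_layout(layout: ChannelLayout, method: str = "delaunay",
                          distance_threshold: float | None = None,
                          ) -> dict[str, set[str]]:
    """Channel neighborhoods from flattened electrode positions.

    ``delaunay`` links channels sharing a triangulation edge (first-order
    neighbors); ``distance`` links channels closer than the threshold.
    Every channel is its own neighbor; the map is symmetric.
    """
    names = list(layout.names)
    pos = layout.pos2d
    adj: dict[str, set[str]] = {ch: {ch} for ch in names}
    if method == "delaunay":
        if len(names) < 4:
            for ch in names:
                adj[ch] = set(names)
            return adj
        tri = Delaunay(pos)
        for simplex in tri.simplices:
            for i, j in combinations(simplex, 2):
                adj[names[i]].add(names[j])
                adj[names[j]].add(names[i])
    elif method == "distance":
        if distance_threshold is None:
            raise ValueError("distance method needs distance_threshold")
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        for i, ch in enumerate(names):
            adj[ch] |= {names[j] for j in np.flatnonzero(d[i] <= distance_threshold)}
    else:
        raise ValueError(f"unknown adjacency method {method!r}")
    return adj


def adjacency_matrix(adj: dict[str, set[str]], ch_names: list[str]) -> np.ndarray:
    """Boolean channel x channel matrix (diagonal True) from a neighbor map."""
    idx = {ch: i for i, ch in enumerate(ch_names)}
    m = np.zeros((len(ch_names), len(ch_names)), bool)
    for ch, nbrs in adj.items():
        for nb in nbrs:
            m[idx[ch], idx[nb]] = True
    return m | m.T


def searchlight(pseudo: PseudoTrialSet, adjacency: dict[str, set[str]],
                scheme: SchemeSpec,
                config: ClassifierConfig = ClassifierConfig()) -> DecodingResult:
    """Channel-wise decoding on each channel plus its neighbors.

    Returns accuracy with shape (participants, folds, channels, times); use
    :meth:`DecodingResult.channel_mean` for the all-channel average used in
    onset estimation.
    """
    names = list(pseudo.layout.names)
    missing = [ch for ch in names if ch not in adjacency]
    if missing:
        raise SchemeError(f"adjacency missing channels: {missing}")
    per_channel = []
    for ch in names:
        sel = sorted(names.index(nb) for nb in adjacency[ch])
        res = loso_timecourse(pseudo, scheme, config, channels=sel)
        per_channel.append(res.accuracy)
    acc = np.stack(per_channel, axis=2)
    folds = _scheme_folds(scheme, pseudo.metadata[0])
    return DecodingResult(accuracy=acc, scheme=scheme, chance=scheme.chance,
                          times_ms=pseudo.times_ms, folds=folds,
                          ch_names=names, meta={"searchlight": True})


def roi_map_from_layout(layout: ChannelLayout) -> dict[str, list[str]]:
    """Six scalp regions: left/right x anterior/central/posterior.

    Channels split by the sign of the left-right coordinate (midline
    channels join both sides) and by terciles of the anterior-posterior
    coordinate.
    """
    names = list(layout.names)
    x, y = layout.pos2d[:, 0], layout.pos2d[:, 1]
    lo, hi = np.quantile(y, [1 / 3, 2 / 3])
    rois: dict[str, list[str]] = {k: [] for k in ROI_LABELS}
    eps = 1e-6 * max(1.0, np.abs(x).max())
    for i, ch in enumerate(names):
        band = "P" if y[i] < lo else ("C" if y[i] < hi else "A")
        if x[i] < -eps:
            sides = ["L"]
        elif x[i] > eps:
            sides = ["R"]
        else:
            sides = ["L", "R"]
        for side in sides:
            rois[side + band].append(ch)
    if any(len(v) == 0 for v in rois.values()):
        raise SchemeError("a region of interest is empty for this layout")
    return rois


def roi_timecourse(pseudo: PseudoTrialSet, roi_map: dict[str, list[str]],
                   scheme: SchemeSpec,
                   config: ClassifierConfig = ClassifierConfig(),
                   ) -> dict[str, DecodingResult]:
    """Decoding restricted to each region of interest's channels."""
    names = list(pseudo.layout.names)
    out = {}
    for roi, chans in roi_map.items():
        if not chans:
            raise SchemeError(f"ROI {roi!r} is empty")
        missing = [c for c in chans if c not in names]
        if missing:
            raise SchemeError(f"ROI {roi!r} channels not in montage: {missing}")
        sel = sorted(names.index(c) for c in chans)
        res = loso_timecourse(pseudo, scheme, config, channels=sel)
        res.meta["roi"] = roi
        out[roi] = res
    return out
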