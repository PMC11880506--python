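"""Stimulus catalogue, 2AFC session scheduling, and behavioral summaries.

The experiment shows 32 face images (8 identities, 4 per sex, each
photographed with a happy, angry, sad, and neutral expression) in a
two-alternative forced-choice expression-categorization task.  Each image is
repeated 12 times; on each trial the veridical expression is paired with one
of the three other expressions as the foil, each foil serving 4 times per
image, with the response key side balanced within (image, foil) pairs.
Incorrectly answered trials are re-inserted later in the sequence so that
every image ends with the full count of correct trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _sps

EXPRESSIONS = ("happy", "angry", "sad", "neutral")
SEXES = ("male", "female")

#: Default identity labels: four male, four female.
DEFAULT_IDENTITIES = {
    "M1": "male", "M2": "male", "M3": "male", "M4": "male",
    "F1": "female", "F2": "female", "F3": "female", "F4": "female",
}


class InvalidDesignError(ValueError):
    """Raised when a stimulus catalogue or schedule violates the design."""


@dataclass(frozen=True)
class Stimulus:
    image_id: str
    identity: str
    sex: str
    expression: str


@dataclass
class StimulusSet:
    """The 32-image catalogue with optional rasters and embeddings.

    ``rasters`` maps image_id -> 2-D grayscale array (uniform shape);
    ``embeddings`` maps image_id -> 1-D descriptor vector (default length
    128).  Both are optional; they feed the image-property model RDMs.
    """

    stimuli: list[Stimulus]
    rasters: dict[str, np.ndarray] = field(default_factory=dict)
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {s.identity for s in self.stimuli}
        if len(ids) != 8:
            raise InvalidDesignError(f"expected 8 identities, got {len(ids)}")
        by_sex = {sex: {s.identity for s in self.stimuli if s.sex == sex}
                  for sex in SEXES}
        if any(len(v) != 4 for v in by_sex.values()):
            raise InvalidDesignError("expected 4 identities per sex")
        image_ids = [s.image_id for s in self.stimuli]
        if len(set(image_ids)) != 32 or len(image_ids) != 32:
            raise InvalidDesignError("expected 32 unique image ids")
        pairs = {(s.identity, s.expression) for s in self.stimuli}
        if len(pairs) != 32:
            raise InvalidDesignError(
                "every (identity, expression) pair must occur exactly once")

    @property
    def image_ids(self) -> list[str]:
        return [s.image_id for s in self.stimuli]

    def attribute(self, image_id: str) -> Stimulus:
        return next(s for s in self.stimuli if s.image_id == image_id)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.image_id, s.identity, s.sex, s.expression) for s in self.stimuli],
            columns=["image_id", "identity", "sex", "expression"],
        )

    def sex_of(self, identity: str) -> str:
        return next(s.sex for s in self.stimuli if s.identity == identity)

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "stimuli": [vars(s) for s in self.stimuli],
            "embeddings": {k: v.tolist() for k, v in self.embeddings.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "StimulusSet":
        with open(path) as fh:
            payload = json.load(fh)
        stimuli = [Stimulus(**rec) for rec in payload["stimuli"]]
        emb = {k: np.asarray(v, float) for k, v in payload.get("embeddings", {}).items()}
        return cls(stimuli=stimuli, embeddings=emb)


def build_stimulus_set(identity_labels: dict[str, str] | None = None,
                       seed: int = 0) -> StimulusSet:
    """Build the full 8-identity x 4-expression catalogue.

    Parameters
    ----------
    identity_labels
        Mapping identity label -> sex ("male"/"female"); exactly 8 labels,
        4 per sex.  Defaults to :data:`DEFAULT_IDENTITIES`.
    seed
        Kept for interface symmetry with the generators; the catalogue
        itself is a deterministic Cartesian product.
    """
    labels = dict(identity_labels) if identity_labels is not None else dict(DEFAULT_IDENTITIES)
    if len(labels) != 8:
        raise InvalidDesignError(f"need exactly 8 identity labels, got {len(labels)}")
    for sex in SEXES:
        n = sum(1 for v in labels.values() if v == sex)
        if n != 4:
            raise InvalidDesignError(f"need 4 {sex} identities, got {n}")
    bad = {v for v in labels.values()} - set(SEXES)
    if bad:
        raise InvalidDesignError(f"unknown sex labels: {bad}")
    stimuli = [
        Stimulus(image_id=f"{ident}_{expr}", identity=ident, sex=sex, expression=expr)
        for ident, sex in labels.items()
        for expr in EXPRESSIONS
    ]
    return StimulusSet(stimuli=stimuli)


TRIAL_COLUMNS = [
    "trial_index", "image_id", "identity", "sex", "expression",
    "foil_expression", "correct_key_side", "is_reinserted",
    "chosen_expression", "correct", "rt",
]


def schedule_session(stimulus_set: StimulusSet, repetitions: int = 12,
                     seed: int = 0) -> pd.DataFrame:
    """Build the randomized, balanced trial table for one session.

    Each image appears ``repetitions`` times; each of its 3 possible foil
    expressions is used repetitions/3 times, and within each (image, foil)
    pair the correct-choice key side alternates (an even split when the
    per-pair count is even).  Rows follow the column dictionary in
    :data:`TRIAL_COLUMNS`; response columns are NaN until filled by
    :func:`simulate_responder` or imported data.
    """
    if repetitions % 3 != 0:
        raise InvalidDesignError(
            f"repetitions must be divisible by 3 for foil balance, got {repetitions}")
    rng = np.random.default_rng(seed)
    per_foil = repetitions // 3
    rows = []
    for s in stimulus_set.stimuli:
        foils = [e for e in EXPRESSIONS if e != s.expression]
        for foil in foils:
            for k in range(per_foil):
                side = ("left", "right")[k % 2]
                rows.append((s.image_id, s.identity, s.sex, s.expression, foil, side))
    order = rng.permutation(len(rows))
    table = pd.DataFrame(
        [rows[i] for i in order],
        columns=["image_id", "identity", "sex", "expression",
                 "foil_expression", "correct_key_side"],
    )
    table.insert(0, "trial_index", np.arange(len(table)))
    table["is_reinserted"] = False
    table["chosen_expression"] = pd.Series([pd.NA] * len(table), dtype="object")
    table["correct"] = pd.Series([pd.NA] * len(table), dtype="object")
    table["rt"] = np.nan
    return table[TRIAL_COLUMNS]


def simulate_responder(trial_table: pd.DataFrame,
                       accuracy_profile: dict[str, float],
                       rt_profile: dict[str, tuple[float, float]],
                       seed: int = 0,
                       max_attempts_per_image: int = 1000) -> pd.DataFrame:
    """Fill responses; re-insert error trials until every image has R correct.

    ``accuracy_profile`` maps expression -> P(correct choice);
    ``rt_profile`` maps expression -> (mean, sd) of a truncated-normal RT in
    seconds.  An incorrect trial is cloned at a uniformly random later
    position in the remaining sequence, flagged ``is_reinserted``.  On an
    incorrect choice the recorded response is the foil expression.
    """
    for expr in EXPRESSIONS:
        if expr not in accuracy_profile or expr not in rt_profile:
            raise ValueError(f"profiles must cover expression {expr!r}")
        if accuracy_profile[expr] <= 0.0:
            raise ValueError(
                f"P(correct)=0 for {expr!r} cannot terminate; raise accuracy")
    rng = np.random.default_rng(seed)
    queue = [dict(row) for _, row in trial_table.iterrows()]
    done: list[dict] = []
    attempts: dict[str, int] = {}
    i = 0
    while i < len(queue):
        row = dict(queue[i])
        expr = row["expression"]
        attempts[row["image_id"]] = attempts.get(row["image_id"], 0) + 1
        if attempts[row["image_id"]] > max_attempts_per_image:
            raise RuntimeError(
                f"image {row['image_id']} exceeded {max_attempts_per_image} attempts")
        correct = bool(rng.random() < accuracy_profile[expr])
        mu, sd = rt_profile[expr]
        rt = float(max(0.15, rng.normal(mu, sd)))
        row["chosen_expression"] = expr if correct else row["foil_expression"]
        row["correct"] = correct
        row["rt"] = rt
        done.append(row)
        if not correct:
            clone = dict(queue[i])
            clone["is_reinserted"] = True
            pos = int(rng.integers(i + 1, len(queue) + 1))
            queue.insert(pos, clone)
        i += 1
    out = pd.DataFrame(done)
    out["trial_index"] = np.arange(len(out))
    return out[TRIAL_COLUMNS]


class MissingResponsesError(ValueError):
    """Raised when behavioral summaries are requested without responses."""


@dataclass
class BehavioralReport:
    """Cohort behavioral summary (first-presentation trials only).

    confusion: 4x4 DataFrame of mean percentages, rows = true expression,
    columns = chosen expression; each row sums to 100.
    accuracy: per-expression mean and sd of participant accuracies.
    median_rt: participants x expressions DataFrame of median RTs (seconds).
    rt_tests: Wilcoxon signed-rank records for all 6 expression pairs,
    p-values uncorrected.
    """

    confusion: pd.DataFrame
    accuracy: pd.DataFrame
    median_rt: pd.DataFrame
    rt_tests: pd.DataFrame
    overall_accuracy: float

    def median_rt_ms(self) -> pd.DataFrame:
        return self.median_rt * 1000.0


def behavioral_summary(trial_tables: list[pd.DataFrame]) -> BehavioralReport:
    """Summarize responses across participants.

    Re-inserted trials are excluded, so the summary reflects first
    presentations only.  The RT comparison is a Wilcoxon signed-rank test on
    per-participant median RTs for each of the 6 expression pairs.
    """
    if len(trial_tables) < 2:
        raise ValueError("need at least 2 participants for paired RT tests")
    firsts = []
    for p, tt in enumerate(trial_tables):
        if tt["correct"].isna().any() or tt["rt"].isna().any():
            raise MissingResponsesError(f"participant {p} has unfilled responses")
        ft = tt.loc[~tt["is_reinserted"]].copy()
        ft["participant"] = p
        firsts.append(ft)
    allt = pd.concat(firsts, ignore_index=True)
    allt["correct"] = allt["correct"].astype(bool)

    # confusion: per participant percentage of each chosen category per true
    # expression, then averaged across participants
    conf_parts = []
    for p, grp in allt.groupby("participant"):
        ct = pd.crosstab(grp["expression"], grp["chosen_expression"], normalize="index") * 100.0
        ct = ct.reindex(index=EXPRESSIONS, columns=EXPRESSIONS, fill_value=0.0)
        conf_parts.append(ct)
    confusion = sum(conf_parts) / len(conf_parts)

    acc_pp = allt.groupby(["participant", "expression"])["correct"].mean().unstack()
    acc_pp = acc_pp.reindex(columns=EXPRESSIONS)
    accuracy = pd.DataFrame({"mean": acc_pp.mean(axis=0), "sd": acc_pp.std(axis=0, ddof=1)})

    med_rt = allt.groupby(["participant", "expression"])["rt"].median().unstack()
    med_rt = med_rt.reindex(columns=EXPRESSIONS)

    records = []
    for a, b in combinations(EXPRESSIONS, 2):
        diffs = med_rt[a] - med_rt[b]
        if np.allclose(diffs, 0):
            stat, p = 0.0, 1.0
        else:
            res = _sps.wilcoxon(med_rt[a], med_rt[b])
            stat, p = float(res.statistic), float(res.pvalue)
        records.append({"pair": f"{a}-{b}", "statistic": stat, "p": p})
    rt_tests = pd.DataFrame(records)

    overall = float(allt.groupby("participant")["correct"].mean().mean())
    return BehavioralReport(confusion=confusion, accuracy=accuracy,
                            median_rt=med_rt, rt_tests=rt_tests,
                            overall_accuracy=overall)
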