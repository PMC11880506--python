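"""Synthetic multi-participant EEG cohorts with known ground truth.

The generator emulates the study's data shape — 24 participants, 64
channels, epochs from -200 to 1200 ms at 200 Hz (280 samples), 32 stimuli
repeated 12 times — and plants condition-specific spatiotemporal patterns on
top of temporally autocorrelated Gaussian noise.  An effect is a per-level
multivariate channel pattern gated by a Hann window in time; patterns marked
``shared`` are identical for every participant, which is precisely what
leave-one-participant-out decoding can exploit, while non-shared patterns
are redrawn per participant and are invisible to cross-participant
classifiers.  Synthetic stimulus rasters and face-descriptor embeddings with
controllable attribute structure feed the image-property model RDMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import design as _design
from ._seeding import int_seed, rng_for
from .design import StimulusSet
from .montage import ChannelLayout, layout_for


class ConfigError(ValueError):
    """Raised for invalid cohort or effect configurations."""


@dataclass
class EffectSpec:
    """A planted condition effect.

    attribute
        Which stimulus attribute the pattern depends on: ``sex`` (2 levels),
        ``identity`` (8), ``expression`` (4), or ``image`` (32).
    onset_ms, duration_ms
        Temporal support of the Hann gate, relative to stimulus onset.
    amplitude
        Peak pattern amplitude in signal units (same units as the noise sd,
        i.e. microvolt-scale).
    topography
        Optional per-channel weight vector confining the effect to part of
        the scalp; defaults to a uniform topography.
    shared
        If True (default) the per-level patterns are common to all
        participants; if False they are redrawn per participant, removing
        any cross-participant decodable signal.
    pattern_seed
        Offsets the pattern substream so distinct effects on the same
        attribute are independent.
    """

    attribute: str
    onset_ms: float
    duration_ms: float
    amplitude: float
    topography: np.ndarray | None = None
    shared: bool = True
    pattern_seed: int = 0

    def __post_init__(self) -> None:
        if self.attribute not in ("sex", "identity", "expression", "image"):
            raise ConfigError(f"unknown attribute {self.attribute!r}")
        if self.amplitude < 0:
            raise ConfigError("amplitude must be >= 0")
        if self.duration_ms <= 0:
            raise ConfigError("duration must be positive")
        if self.topography is not None and not np.all(np.isfinite(self.topography)):
            raise ConfigError("topography must be finite")


@dataclass
class CohortConfig:
    """Cohort dimensions and noise model; defaults match the study design."""

    n_participants: int = 24
    n_channels: int = 64
    sfreq: float = 200.0
    tmin: float = -0.2           # seconds
    tmax: float = 1.2
    repetitions: int = 12
    noise_sd: float = 1.0
    noise_smoothing_ms: float = 20.0   # Gaussian kernel sigma along time
    effects: list[EffectSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_channels < 1:
            raise ConfigError("participant and channel counts must be positive")
        if self.sfreq <= 0 or self.noise_sd < 0:
            raise ConfigError("sfreq must be positive, noise_sd non-negative")
        if not (self.tmin <= 0 < self.tmax):
            raise ConfigError("epoch window must contain time 0")
        for eff in self.effects:
            if eff.onset_ms < self.tmin * 1000 or \
                    eff.onset_ms + eff.duration_ms > self.tmax * 1000:
                raise ConfigError(
                    f"effect on {eff.attribute!r} at {eff.onset_ms} ms extends "
                    "outside the epoch window")

    @property
    def n_times(self) -> int:
        # half-open [tmin, tmax) grid: 280 samples for the default window
        return int(round((self.tmax - self.tmin) * self.sfreq))

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_times) / self.sfreq


@dataclass
class EpochsCollection:
    """Per-participant epoched data with aligned trial metadata.

    data[p] has shape (n_trials, n_channels, n_times); metadata[p] is the
    trial table row-aligned to data[p]; times are in seconds on a shared
    grid; the channel layout is common to all participants.
    """

    data: list[np.ndarray]
    metadata: list[pd.DataFrame]
    times: np.ndarray
    sfreq: float
    layout: ChannelLayout

    def __post_init__(self) -> None:
        n_ch = {d.shape[1] for d in self.data}
        if len(n_ch) > 1:
            raise ValueError("channel count must be uniform across participants")
        for d, md in zip(self.data, self.metadata):
            if d.shape[0] != len(md):
                raise ValueError("metadata length must equal trial count")
            if d.shape[2] != len(self.times):
                raise ValueError("time axis mismatch")

    @property
    def n_participants(self) -> int:
        return len(self.data)

    @property
    def ch_names(self) -> list[str]:
        return list(self.layout.names)

    @property
    def times_ms(self) -> np.ndarray:
        return self.times * 1000.0


def _level_of(row: pd.Series, attribute: str) -> str:
    return row["image_id"] if attribute == "image" else row[attribute]


def _pattern(master_seed: int, eff: EffectSpec, level: str,
             n_channels: int, participant: int | None) -> np.ndarray:
    keys = ["pattern", eff.attribute, eff.pattern_seed, level]
    if participant is not None:
        keys.append(("participant", participant))
    v = rng_for(master_seed, *keys).standard_normal(n_channels)
    return v / np.sqrt(np.mean(v**2))     # unit RMS over channels


def _hann_gate(times_s: np.ndarray, onset_ms: float, duration_ms: float) -> np.ndarray:
    t_ms = times_s * 1000.0
    gate = np.zeros_like(t_ms)
    inside = (t_ms >= onset_ms) & (t_ms < onset_ms + duration_ms)
    phase = (t_ms[inside] - onset_ms) / duration_ms
    gate[inside] = np.sin(np.pi * phase) ** 2
    return gate


def generate_cohort(config: CohortConfig, stimulus_set: StimulusSet,
                    ) -> tuple[EpochsCollection, dict]:
    """Generate an epoched cohort plus a ground-truth record.

    Each trial's signal is the sum over effects of
    ``amplitude * pattern(level) * topography * hann(onset, duration)``
    plus temporally smoothed Gaussian noise of standard deviation
    ``noise_sd`` per channel and sample.  Trial order follows a balanced
    session schedule drawn independently per participant.
    """
    layout = layout_for(config.n_channels)
    times = config.times
    gates = [_hann_gate(times, e.onset_ms, e.duration_ms) for e in config.effects]
    topos = []
    for e in config.effects:
        if e.topography is None:
            topo = np.ones(config.n_channels)
        else:
            topo = np.asarray(e.topography, float)
            if topo.shape != (config.n_channels,):
                raise ConfigError("topography length must equal n_channels")
        topos.append(topo)

    data, metadata = [], []
    for p in range(config.n_participants):
        sched = _design.schedule_session(
            stimulus_set, repetitions=config.repetitions,
            seed=int_seed(config.seed, "schedule", p))
        n_trials = len(sched)
        noise_rng = rng_for(config.seed, "noise", p)
        x = noise_rng.standard_normal((n_trials, config.n_channels, config.n_times))
        sigma_samp = config.noise_smoothing_ms / 1000.0 * config.sfreq
        if sigma_samp > 0:
            x = gaussian_filter1d(x, sigma=sigma_samp, axis=-1)
            sd = x.std()
            if sd > 0:
                x *= config.noise_sd / sd
        else:
            x *= config.noise_sd

        for eff, gate, topo in zip(config.effects, gates, topos):
            if eff.amplitude == 0:
                continue
            levels = sched.apply(lambda r: _level_of(r, eff.attribute), axis=1)
            for level in levels.unique():
                pat = _pattern(config.seed, eff, level, config.n_channels,
                               None if eff.shared else p)
                contrib = eff.amplitude * (pat * topo)[:, None] * gate[None, :]
                idx = np.flatnonzero((levels == level).to_numpy())
                x[idx] += contrib
        data.append(x.astype(np.float32))
        metadata.append(sched)

    epochs = EpochsCollection(data=data, metadata=metadata, times=times,
                              sfreq=config.sfreq, layout=layout)
    truth = {
        "seed": config.seed,
        "effects": [
            {"attribute": e.attribute, "onset_ms": e.onset_ms,
             "duration_ms": e.duration_ms, "amplitude": e.amplitude,
             "shared": e.shared}
            for e in config.effects
        ],
    }
    return epochs, truth


def posterior_topography(layout: ChannelLayout, sharpness: float = 4.0) -> np.ndarray:
    """Smooth weight map concentrated on posterior (negative-y) channels."""
    y = layout.pos2d[:, 1]
    y = (y - y.mean()) / (y.std() + 1e-12)
    return 1.0 / (1.0 + np.exp(sharpness * y))


def generate_images(stimulus_set: StimulusSet,
                    image_size: tuple[int, int] = (32, 32),
                    structure_weights: dict[str, float] | None = None,
                    noise_weight: float = 1.0,
                    seed: int = 0) -> dict[str, np.ndarray]:
    """Synthetic grayscale rasters standing in for the face photographs.

    Each raster is a weighted sum of an identity template, a sex template,
    an expression template, and pixel noise: ``structure_weights`` (keys
    ``identity``, ``sex``, ``expression``) control how strongly the rasters
    encode each attribute, so image-similarity RDMs can be made to correlate
    with chosen attribute models by construction.
    """
    h, w = image_size
    if h <= 0 or w <= 0:
        raise ValueError("image size must be positive")
    weights = {"identity": 1.0, "sex": 0.5, "expression": 0.5}
    if structure_weights:
        weights.update(structure_weights)
    templates: dict[tuple[str, str], np.ndarray] = {}

    def template(kind: str, level: str) -> np.ndarray:
        key = (kind, level)
        if key not in templates:
            templates[key] = rng_for(seed, "img-template", kind, level).standard_normal((h, w))
        return templates[key]

    rasters = {}
    for s in stimulus_set.stimuli:
        img = (weights["identity"] * template("identity", s.identity)
               + weights["sex"] * template("sex", s.sex)
               + weights["expression"] * template("expression", s.expression))
        img = img + noise_weight * rng_for(seed, "img-noise", s.image_id).standard_normal((h, w))
        rasters[s.image_id] = img
    return rasters


def generate_embeddings(stimulus_set: StimulusSet, dim: int = 128,
                        identity_clustering: float = 1.0,
                        seed: int = 0) -> dict[str, np.ndarray]:
    """Synthetic face-descriptor vectors (default 128-dimensional).

    Vectors are Gaussian with identity-specific cluster means scaled by
    ``identity_clustering``; at 0 the embeddings carry no identity
    structure, at large values same-identity images are nearly collinear.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    out = {}
    for s in stimulus_set.stimuli:
        mu = rng_for(seed, "emb-mean", s.identity).standard_normal(dim)
        eps = rng_for(seed, "emb-noise", s.image_id).standard_normal(dim)
        out[s.image_id] = identity_clustering * mu + eps
    return out
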