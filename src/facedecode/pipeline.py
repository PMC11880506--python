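"""End-to-end orchestration: simulate -> preprocess -> decode -> rsa -> stats.

A :class:`RunConfig` holds every stage parameter (defaults are the study's
values), round-trips losslessly through YAML, and drives
:func:`run_pipeline`, which writes per-stage HDF5/JSON outputs plus a
provenance record into an output directory.  Re-running with an unchanged
config reuses cached stage outputs, so runs are idempotent; all randomness
descends from the single master seed via named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import containers, decode, preprocess, rsa, stats, synth
from ._seeding import int_seed
from .design import build_stimulus_set
from .synth import CohortConfig, EffectSpec

logger = logging.getLogger("facedecode")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Every stage parameter in one declarative record."""

    output_dir: str = "facedecode_run"
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_preprocess: bool = True
    run_decode: bool = True
    run_rsa: bool = False
    run_stats: bool = True
    # cohort
    n_participants: int = 24
    n_channels: int = 64
    sfreq: float = 200.0
    tmin: float = -0.2
    tmax: float = 1.2
    repetitions: int = 12
    noise_sd: float = 1.0
    noise_smoothing_ms: float = 20.0
    effects: list[dict] = field(default_factory=list)
    # preprocessing
    apply_filter: bool = False
    filter_low: float = 0.1
    filter_high: float = 40.0
    baseline: tuple[float, float] | None = (-0.2, 0.0)
    bin_size: int = 3
    # decoding
    schemes: list[str] = field(default_factory=lambda: ["identity", "sex", "emotion"])
    classifier_solver: str = "lsqr"
    classifier_shrinkage: str = "auto"
    # statistics
    smoothing_window_ms: float = 35.0
    apply_smoothing: bool = True
    n_perm: int = 10000
    cluster_alpha: float = 0.05
    prior_scale: float = 0.707
    interval_halfwidth: float = 0.5
    bf_threshold: float = 10.0

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["baseline"] = list(self.baseline) if self.baseline is not None else None
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("baseline") is not None:
            d["baseline"] = tuple(d["baseline"])
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("output_dir")
        return hashlib.sha1(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()

    def cohort_config(self) -> CohortConfig:
        effects = []
        for e in self.effects:
            e = dict(e)
            topo = e.pop("topography", None)
            spec = EffectSpec(**e)
            if topo == "posterior":
                from .montage import layout_for
                spec.topography = synth.posterior_topography(layout_for(self.n_channels))
            elif topo is not None:
                spec.topography = np.asarray(topo, float)
            effects.append(spec)
        return CohortConfig(
            n_participants=self.n_participants, n_channels=self.n_channels,
            sfreq=self.sfreq, tmin=self.tmin, tmax=self.tmax,
            repetitions=self.repetitions, noise_sd=self.noise_sd,
            noise_smoothing_ms=self.noise_smoothing_ms, effects=effects,
            seed=int_seed(self.seed, "simulate"))

    @classmethod
    def reduced(cls, **overrides) -> "RunConfig":
        """Desk-scale preset: 6 participants, 16 channels, 50 timepoints."""
        base = dict(n_participants=6, n_channels=16, tmin=-0.05, tmax=0.2,
                    repetitions=6, n_perm=1000)
        base.update(overrides)
        return cls(**base)


def _classifier(config: RunConfig) -> decode.ClassifierConfig:
    shr = config.classifier_shrinkage
    if isinstance(shr, str) and shr not in ("auto",):
        shr = float(shr)
    return decode.ClassifierConfig(solver=config.classifier_solver, shrinkage=shr)


def _cached(path: Path, stamp: Path, chash: str) -> bool:
    return path.exists() and stamp.exists() and stamp.read_text() == chash


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the report bundle.

    Stage outputs land in ``config.output_dir``; a stage whose output
    already exists for the same config hash is loaded instead of recomputed.
    Raises :class:`PipelineError` when a stage's dependency is disabled and
    its output is absent.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report: dict = {"config_hash": chash}
    provenance = {"config": asdict(config), "config_hash": chash,
                  "stages_run": []}

    stim = build_stimulus_set(seed=config.seed)

    epochs = None
    epochs_path, epochs_stamp = out / "epochs.h5", out / "epochs.hash"
    if config.run_simulate:
        if _cached(epochs_path, epochs_stamp, chash):
            logger.info("simulate: cached")
            epochs = containers.load_epochs(epochs_path)
        else:
            logger.info("simulate: generating cohort")
            epochs, truth = synth.generate_cohort(config.cohort_config(), stim)
            containers.save_epochs(epochs_path, epochs)
            (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
            epochs_stamp.write_text(chash)
            provenance["stages_run"].append("simulate")

    pseudo = None
    pseudo_path, pseudo_stamp = out / "pseudo.h5", out / "pseudo.hash"
    if config.run_preprocess:
        if epochs is None:
            raise PipelineError("preprocess requires the simulate stage (or its output)")
        if _cached(pseudo_path, pseudo_stamp, chash):
            logger.info("preprocess: cached")
            pseudo = containers.load_pseudo(pseudo_path)
        else:
            logger.info("preprocess: baseline + binning")
            baseline = config.baseline
            if baseline is not None:
                baseline = (max(baseline[0], config.tmin), baseline[1])
                if baseline[1] <= baseline[0]:
                    baseline = None
            pseudo = preprocess.preprocess_cohort(
                epochs, filter_band=(config.filter_low, config.filter_high),
                apply_filter=config.apply_filter, baseline=baseline,
                bin_size=config.bin_size, seed=int_seed(config.seed, "bins"))
            containers.save_pseudo(pseudo_path, pseudo)
            pseudo_stamp.write_text(chash)
            provenance["stages_run"].append("preprocess")

    results: dict[str, decode.DecodingResult] = {}
    if config.run_decode:
        if pseudo is None:
            raise PipelineError("decode requires the preprocess stage")
        clf = _classifier(config)
        for name in config.schemes:
            spec = (decode.scheme("emotion_pair", tuple(name.split(":")[1].split("-")))
                    if name.startswith("pair:") else decode.scheme(name))
            rpath = out / f"decoding_{name.replace(':', '_')}.h5"
            rstamp = rpath.with_suffix(".hash")
            if _cached(rpath, rstamp, chash):
                logger.info("decode[%s]: cached", name)
                results[name] = containers.load_decoding(rpath)
            else:
                logger.info("decode[%s]: LOSO time course", name)
                results[name] = decode.loso_timecourse(pseudo, spec, clf)
                containers.save_decoding(rpath, results[name])
                rstamp.write_text(chash)
                provenance["stages_run"].append(f"decode:{name}")

    rsa_out = None
    if config.run_rsa:
        if not config.run_decode:
            raise PipelineError("rsa requires the decode stage to be enabled")
        rpath, rstamp = out / "neural_rdm.h5", out / "neural_rdm.hash"
        if _cached(rpath, rstamp, chash):
            logger.info("rsa: cached")
            neural = containers.load_rdm_series(rpath)
        else:
            logger.info("rsa: pairwise neural RDM series")
            neural = rsa.neural_rdm_series(pseudo, stimulus_order=stim.image_ids,
                                           config=_classifier(config))
            containers.save_rdm_series(rpath, neural)
            rstamp.write_text(chash)
            provenance["stages_run"].append("rsa")
        rasters = synth.generate_images(stim, seed=int_seed(config.seed, "images"))
        embeddings = synth.generate_embeddings(stim, seed=int_seed(config.seed, "emb"))
        image_model = rsa.max_crosscorr_rdm(rasters, stimulus_order=stim.image_ids)
        emb_model = rsa.embedding_rdm(embeddings, stimulus_order=stim.image_ids)
        rsa_out = {}
        for attr in ("identity", "sex", "expression"):
            model = rsa.attribute_model_rdm(stim, attribute=attr)
            rsa_out[attr] = {
                "plain": rsa.rsa_correlate(neural, model),
                "partial_image": rsa.rsa_correlate(neural, model,
                                                   covariates=[image_model]),
                "partial_embedding": rsa.rsa_correlate(neural, model,
                                                       covariates=[emb_model]),
            }

    if config.run_stats:
        if not results:
            raise PipelineError("stats requires decoding results")
        inference = {}
        for name, res in results.items():
            bundle = stats.SeriesBundle.from_decoding(res)
            if config.apply_smoothing:
                bundle = bundle.smoothed(config.smoothing_window_ms)
            cl = stats.cluster_permutation(bundle, n_perm=config.n_perm,
                                           seed=int_seed(config.seed, "perm", name))
            bf = stats.bayes_factor_series(bundle, config.prior_scale,
                                           config.interval_halfwidth,
                                           config.bf_threshold)
            op = stats.onset_peak(bf)
            inference[name] = {
                "chance": res.chance,
                "mean_accuracy": float(bundle.values.mean()),
                "clusters": [
                    {"start_ms": c.start_ms, "end_ms": c.end_ms, "mass": c.mass,
                     "p": c.p, "peak_time_ms": c.peak_time_ms, "peak_d": c.peak_d,
                     "sign": c.sign}
                    for c in cl.clusters],
                "onset": op,
                "max_bf": float(bf.bf.max()),
            }
        if rsa_out is not None:
            inference["rsa"] = {
                attr: {variant: float(np.mean(r.rho))
                       for variant, r in variants.items()}
                for attr, variants in rsa_out.items()
            }
        report["inference"] = inference
        (out / "report.json").write_text(json.dumps(report, indent=2))

    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    report["results"] = results
    report["rsa"] = rsa_out
    return report
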