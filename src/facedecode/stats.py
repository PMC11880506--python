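"""Group-level inference on decoding / RSA time courses.

The canonical chain: smooth participant-level series with a 35 ms moving
average (7 samples at 200 Hz), then (i) two-sided one-sample cluster
permutation tests against chance — cluster mass of suprathreshold t values
against a participant-wise sign-flip null (default 10,000 iterations) — and
(ii) per-timepoint interval-null Bayes factors, comparing standardized
effect sizes outside |delta| = 0.5 against inside, under a Cauchy(0, 0.707)
prior, with BF > 10 read as strong evidence.  Onsets are the first
suprathreshold timepoint and peaks the first local maximum of evidence
within that run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy import stats as _sps
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


@dataclass
class SeriesBundle:
    """Participant-resolved series against a known null reference.

    values: (n_participants, n_times) or (n_participants, n_channels,
    n_times); chance is the null value (scheme chance for accuracies, 0 for
    Fisher z); times_ms aligns the last axis.
    """

    values: np.ndarray
    chance: float
    times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if np.isnan(self.values).any():
            raise ValueError("series contain missing values")
        if self.values.shape[-1] != len(self.times_ms):
            raise ValueError("time axis mismatch")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def sfreq(self) -> float:
        dt = np.diff(self.times_ms)
        return 1000.0 / float(dt[0])

    def smoothed(self, window_ms: float = 35.0) -> "SeriesBundle":
        return SeriesBundle(values=moving_average(self.values, window_ms, self.sfreq),
                            chance=self.chance, times_ms=self.times_ms)

    @classmethod
    def from_decoding(cls, result) -> "SeriesBundle":
        return cls(values=result.participant_timecourse(), chance=result.chance,
                   times_ms=result.times_ms)

    @classmethod
    def from_rsa(cls, result) -> "SeriesBundle":
        return cls(values=result.z, chance=0.0, times_ms=result.times_ms)


def moving_average(series: np.ndarray, window_ms: float = 35.0,
                   sfreq: float = 200.0) -> np.ndarray:
    """Centered moving average along the last axis; edges shrink the window.

    The window is converted to an odd sample count (35 ms at 200 Hz spans 7
    consecutive timepoints).
    """
    n = int(round(window_ms / 1000.0 * sfreq))
    if n < 1:
        raise ValueError(f"window {window_ms} ms is shorter than one sample")
    if n % 2 == 0:
        n += 1
    h = n // 2
    x = np.asarray(series, float)
    T = x.shape[-1]
    csum = np.cumsum(x, axis=-1)
    out = np.empty_like(x)
    for i in range(T):
        lo, hi = max(0, i - h), min(T, i + h + 1)
        total = csum[..., hi - 1] - (csum[..., lo - 1] if lo > 0 else 0)
        out[..., i] = total / (hi - lo)
    return out


def effect_size_series(bundle: SeriesBundle) -> np.ndarray:
    """Per-timepoint one-sample Cohen's d of (value - chance).

    Zero-variance points yield signed infinity (flagged, not raised).
    """
    if bundle.n_participants < 2:
        raise ValueError("need at least 2 participants")
    d = bundle.values - bundle.chance
    m, s = d.mean(axis=0), d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = m / s
    out = np.where((s == 0) & (m == 0), 0.0, out)
    return out


def _tstats(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    s = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
    return np.where((s == 0) & (m == 0), 0.0, t)


@dataclass
class ClusterRecord:
    """One suprathreshold cluster and its permutation p-value."""

    time_indices: np.ndarray
    start_ms: float
    end_ms: float
    mass: float
    p: float
    peak_time_ms: float
    peak_d: float
    sign: int
    channels: list[str] | None = None


@dataclass
class ClusterTestResult:
    clusters: list[ClusterRecord]
    t_obs: np.ndarray
    threshold: float
    null_max_mass: np.ndarray
    n_perm_used: int
    exhaustive: bool

    def significant(self, alpha: float = 0.05) -> list[ClusterRecord]:
        return [c for c in self.clusters if c.p <= alpha]


def _temporal_clusters(mask: np.ndarray) -> list[np.ndarray]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    return [np.asarray(run) for run in np.split(idx, breaks + 1)]


def _spatiotemporal_clusters(mask: np.ndarray, adjacency: np.ndarray,
                             ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Connected components over (channel, time) with spatial adjacency."""
    n_ch, n_t = mask.shape
    pts = np.flatnonzero(mask.ravel())
    if pts.size == 0:
        return []
    pos = {p: k for k, p in enumerate(pts)}
    rows, cols = [], []
    for p in pts:
        c, t = divmod(p, n_t)
        if t + 1 < n_t and mask[c, t + 1]:
            rows.append(pos[p]); cols.append(pos[c * n_t + t + 1])
        for c2 in np.flatnonzero(adjacency[c]):
            if c2 != c and mask[c2, t]:
                rows.append(pos[p]); cols.append(pos[c2 * n_t + t])
    g = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(pts.size, pts.size))
    n_comp, labels = connected_components(g, directed=False)
    out = []
    for comp in range(n_comp):
        members = pts[labels == comp]
        out.append((members // n_t, members % n_t))
    return out


def _max_cluster_mass(t: np.ndarray, thr: float,
                      adjacency: np.ndarray | None) -> float:
    best = 0.0
    for sign in (1, -1):
        mask = sign * t > thr
        if t.ndim == 1:
            for run in _temporal_clusters(mask):
                best = max(best, abs(t[run].sum()))
        else:
            for chans, times in _spatiotemporal_clusters(mask, adjacency):
                best = max(best, abs(t[chans, times].sum()))
    return best


def cluster_permutation(bundle: SeriesBundle, n_perm: int = 10000,
                        cluster_threshold_p: float = 0.05,
                        adjacency: np.ndarray | None = None,
                        seed: int = 0) -> ClusterTestResult:
    """Two-sided one-sample cluster permutation test against chance.

    Per-point one-sample t of (value - chance); points with |t| above the
    two-tailed ``cluster_threshold_p`` quantile are clustered by temporal
    (and spatial, via ``adjacency``) contiguity, positive and negative
    clusters separately.  The null distribution of the maximum absolute
    cluster mass comes from random participant-wise sign flips; each
    cluster's p is the proportion of null maxima at least as large.  With
    few participants the sign-flip space is enumerated exhaustively.
    """
    d = bundle.values - bundle.chance
    n = d.shape[0]
    if n < 5:
        warnings.warn(f"only {n} participants; permutation space is small")
    if d.ndim == 3 and adjacency is None:
        raise ValueError("channel x time input requires an adjacency matrix")
    t_obs = _tstats(d)
    thr = float(_sps.t.ppf(1 - cluster_threshold_p / 2, n - 1))

    exhaustive = 2 ** n <= n_perm
    if exhaustive:
        signs = np.array([[1 if (k >> i) & 1 else -1 for i in range(n)]
                          for k in range(2 ** n)], float)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = np.empty(signs.shape[0])
    flat = d.reshape(n, -1)
    sumsq = (flat ** 2).sum(axis=0)
    for k, s in enumerate(signs):
        m = s @ flat / n
        var = (sumsq - n * m ** 2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = m / np.sqrt(var / n)
        t_p = np.where(np.isfinite(t_p), t_p, 0.0).reshape(t_obs.shape)
        null[k] = _max_cluster_mass(t_p, thr, adjacency)

    def pval(mass: float) -> float:
        if exhaustive:
            return float(np.mean(null >= mass - 1e-12))
        return float((1 + np.sum(null >= mass - 1e-12)) / (len(null) + 1))

    d_series = effect_size_series(bundle)
    records: list[ClusterRecord] = []
    for sign in (1, -1):
        mask = sign * t_obs > thr
        if t_obs.ndim == 1:
            comps = [(None, run) for run in _temporal_clusters(mask)]
        else:
            comps = _spatiotemporal_clusters(mask, adjacency)
        for chans, times in comps:
            if t_obs.ndim == 1:
                tv = t_obs[times]
                mass = float(tv.sum())
                k = times[np.argmax(np.abs(tv))]
                peak_ms = float(bundle.times_ms[k])
                peak_d = float(d_series[k])
                ch_list = None
                tmin, tmax = times.min(), times.max()
            else:
                tv = t_obs[chans, times]
                mass = float(tv.sum())
                kk = np.argmax(np.abs(tv))
                peak_ms = float(bundle.times_ms[times[kk]])
                peak_d = float(d_series[chans[kk], times[kk]])
                ch_list = sorted(set(chans.tolist()))
                tmin, tmax = times.min(), times.max()
            records.append(ClusterRecord(
                time_indices=np.unique(times), start_ms=float(bundle.times_ms[tmin]),
                end_ms=float(bundle.times_ms[tmax]), mass=mass, p=pval(abs(mass)),
                peak_time_ms=peak_ms, peak_d=peak_d, sign=sign, channels=ch_list))
    records.sort(key=lambda r: r.start_ms)
    return ClusterTestResult(clusters=records, t_obs=t_obs, threshold=thr,
                             null_max_mass=null, n_perm_used=len(null),
                             exhaustive=exhaustive)


# ---------------------------------------------------------------------------
# Bayes factors

def interval_null_bf(t: float, n: int, prior_scale: float = 0.707,
                     interval_halfwidth: float = 0.5) -> float:
    """Interval-null Bayes factor from a one-sample t statistic.

    Evidence for standardized effect sizes outside the practically-null
    interval |delta| <= h against inside it, under a non-directional
    Cauchy(0, r) prior: both hypotheses are the truncations of the same
    prior, and their marginal likelihoods are obtained by integrating the
    noncentral-t density of the observed t over the prior.  Integration is
    performed in the prior's CDF domain, where the Cauchy weight is uniform.
    """
    df = n - 1
    r, h = prior_scale, interval_halfwidth
    # saturate extreme statistics (including infinities from zero-variance
    # samples): the BF is monotone in |t| and astronomically past any
    # evidence threshold well before this cap
    t_cap = 50.0
    if not np.isfinite(t):
        t = np.sign(t) * t_cap if t != 0 else 0.0
    t = float(np.clip(t, -t_cap, t_cap))
    sqn = np.sqrt(n)

    def like_u(u):
        delta = r * np.tan(np.pi * (u - 0.5))     # Cauchy quantile
        return _sps.nct.pdf(t, df, delta * sqn)

    u_hi = 0.5 + np.arctan(h / r) / np.pi
    u_lo = 1.0 - u_hi
    p_in = u_hi - u_lo
    p_out = 1.0 - p_in
    inside, err_in = integrate.quad(like_u, u_lo, u_hi, limit=200)
    out_l, err_l = integrate.quad(like_u, 0.0, u_lo, limit=200)
    out_r, err_r = integrate.quad(like_u, u_hi, 1.0, limit=200)
    outside = out_l + out_r
    if not np.isfinite(inside) or not np.isfinite(outside) or inside <= 0:
        raise ArithmeticError(
            f"interval-null integration failed: inside={inside} (err {err_in}), "
            f"outside={outside} (errs {err_l}, {err_r}), t={t}, n={n}")
    return float((outside / p_out) / (inside / p_in))


def point_null_bf(t: float, n: int, prior_scale: float = 0.707) -> float:
    """Plain JZS point-null Bayes factor (Cauchy prior vs delta = 0)."""
    df = n - 1
    if not np.isfinite(t):
        t = np.sign(t) * 50.0 if t != 0 else 0.0
    t = float(np.clip(t, -50.0, 50.0))
    sqn = np.sqrt(n)

    def like_u(u):
        delta = prior_scale * np.tan(np.pi * (u - 0.5))
        return _sps.nct.pdf(t, df, delta * sqn)

    marg, _ = integrate.quad(like_u, 0.0, 1.0, limit=200)
    null = _sps.t.pdf(t, df)
    return float(marg / null)


@dataclass
class BayesSeries:
    """Per-timepoint interval-null Bayes factors."""

    bf: np.ndarray
    times_ms: np.ndarray
    prior_scale: float = 0.707
    interval_halfwidth: float = 0.5
    threshold: float = 10.0
    t_values: np.ndarray | None = None
    n_participants: int | None = None

    @property
    def log10_bf(self) -> np.ndarray:
        return np.log10(self.bf)

    @property
    def above_threshold(self) -> np.ndarray:
        return self.bf > self.threshold


def bayes_factor_series(bundle: SeriesBundle, prior_scale: float = 0.707,
                        interval_halfwidth: float = 0.5,
                        threshold: float = 10.0) -> BayesSeries:
    """Interval-null Bayes factor at every timepoint of a series bundle."""
    if bundle.n_participants < 3:
        raise ValueError("need at least 3 participants")
    if bundle.values.ndim != 2:
        raise ValueError("Bayes series expects participant x time input")
    t = _tstats(bundle.values - bundle.chance)
    bf = np.array([interval_null_bf(tv, bundle.n_participants, prior_scale,
                                    interval_halfwidth) for tv in t])
    return BayesSeries(bf=bf, times_ms=bundle.times_ms, prior_scale=prior_scale,
                       interval_halfwidth=interval_halfwidth, threshold=threshold,
                       t_values=t, n_participants=bundle.n_participants)


# ---------------------------------------------------------------------------
# onsets and peaks

def onset_peak(series: np.ndarray | BayesSeries, times_ms: np.ndarray | None = None,
               threshold: float = 10.0, min_run: int = 1,
               require_positive: bool = True) -> dict:
    """Onset and first-peak latency from a thresholded evidence series.

    Onset is the first timepoint of the first run of at least ``min_run``
    suprathreshold samples; the peak is the first local maximum of the
    series within that run (the run's overall maximum when the run is
    monotone).  The interval-null Bayes factor is non-directional, so when
    the underlying t series is available (a :class:`BayesSeries` input) only
    above-chance evidence counts toward the onset by default — decoding
    onsets are about information emerging, not below-chance dips.  Returns
    ``{"onset_ms": None, ...}`` when nothing exceeds threshold — an explicit
    null result.
    """
    direction_ok = None
    if isinstance(series, BayesSeries):
        values = series.bf
        times_ms = series.times_ms
        threshold = series.threshold
        if require_positive and series.t_values is not None:
            direction_ok = series.t_values > 0
    else:
        values = np.asarray(series, float)
        if times_ms is None:
            raise ValueError("times_ms required for a bare series")
    mask = values > threshold
    if direction_ok is not None:
        mask = mask & direction_ok
    runs = [r for r in _temporal_clusters(mask) if len(r) >= min_run]
    if not runs:
        return {"onset_ms": None, "peak_ms": None, "peak_value": None}
    run = runs[0]
    v = values[run]
    peak_idx = None
    for k in range(len(run)):
        left_ok = k == 0 or v[k] >= v[k - 1]
        right_ok = k == len(run) - 1 or v[k] > v[k + 1]
        if left_ok and right_ok:
            peak_idx = k
            break
    if peak_idx is None:
        peak_idx = int(np.argmax(v))
    return {"onset_ms": float(times_ms[run[0]]),
            "peak_ms": float(times_ms[run[peak_idx]]),
            "peak_value": float(v[peak_idx])}
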