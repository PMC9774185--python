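"""Trace idealization and single-channel activity statistics.

Converts a sampled current record into a contiguous list of integer
conductance-level events by half-amplitude threshold detection, then computes
the standard activity measures: NPo (the time-weighted sum of open levels),
the channel count N from amplitude-histogram peaks, open/closed dwell-time
summaries, exponential-mixture dwell fits, and rate-constant recovery from a
ligand titration of dwell means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .fitting import ExponentialMixture, MixtureFit

__all__ = [
    "EventList",
    "NPoResult",
    "DwellSummary",
    "TitrationRates",
    "estimate_baseline",
    "idealize",
    "compute_npo",
    "estimate_channel_count",
    "npo_result",
    "dwell_summary",
    "fit_exponential_mixture",
    "recover_rates_from_titration",
]


@dataclass
class EventList:
    """Contiguous, non-overlapping idealized sojourns.

    levels : integer number of simultaneously open channels per event.
    starts, durations : ms; events tile [0, total_time] exactly.
    """

    levels: np.ndarray
    starts: np.ndarray
    durations: np.ndarray
    total_time: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        self.starts = np.asarray(self.starts, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if len(self.levels) != len(self.starts) or len(self.levels) != len(self.durations):
            raise ValueError("levels, starts and durations must have equal length")
        if len(self.levels):
            if np.any(self.durations <= 0):
                raise ValueError("event durations must be > 0")
            if np.any(np.diff(self.levels) == 0):
                raise ValueError("consecutive events must differ in level")
            if not np.isclose(self.durations.sum(), self.total_time, rtol=1e-9, atol=1e-6):
                raise ValueError("durations must sum to total_time")
            if not np.allclose(self.starts[1:], self.starts[:-1] + self.durations[:-1],
                               rtol=1e-9, atol=1e-6):
                raise ValueError("events must be contiguous")

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def max_level(self) -> int:
        return int(self.levels.max()) if len(self.levels) else 0

    def time_average_level(self) -> float:
        """Exact time average of the level function (equals NPo)."""
        return float((self.levels * self.durations).sum() / self.total_time)

    @classmethod
    def from_samples(cls, levels: np.ndarray, dt: float) -> "EventList":
        """Collapse a per-sample level sequence into run-length events."""
        levels = np.asarray(levels, dtype=int)
        if levels.size == 0:
            raise ValueError("empty level sequence")
        change = np.flatnonzero(np.diff(levels)) + 1
        bounds = np.concatenate([[0], change, [levels.size]])
        starts = bounds[:-1] * dt
        durations = np.diff(bounds) * dt
        return cls(levels=levels[bounds[:-1]], starts=starts,
                   durations=durations, total_time=levels.size * dt)


@dataclass(frozen=True)
class NPoResult:
    """Channel activity: NPo, estimated channel count N, and Po = NPo/N."""

    NPo: float
    N: int
    Po: float
    total_time: float


@dataclass(frozen=True)
class DwellSummary:
    """Arithmetic open/closed dwell-time summaries (ms), censored sojourns excluded."""

    mean_open: float
    mean_closed: float
    sd_open: float
    sd_closed: float
    n_open_events: int
    n_closed_events: int


def estimate_baseline(trace, noise_sd: float | None = None) -> float:
    """Closed-channel current level: mode of the all-points histogram.

    The closed level is assumed to be the most occupied.  Bin width is
    ``noise_sd / 4`` when the noise amplitude is known (from trace metadata or
    the argument), otherwise Freedman-Diaconis.
    """
    samples = np.asarray(trace.samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty trace")
    if np.ptp(samples) == 0:
        return float(samples[0])
    if noise_sd is None:
        noise_sd = trace.metadata.get("noise_sd") if hasattr(trace, "metadata") else None
    if noise_sd:
        width = noise_sd / 4.0
        nbins = max(int(np.ceil(np.ptp(samples) / width)), 4)
    else:
        iqr = np.subtract(*np.percentile(samples, [75, 25]))
        width = 2 * iqr * samples.size ** (-1 / 3) if iqr > 0 else np.ptp(samples) / 100
        nbins = max(int(np.ceil(np.ptp(samples) / width)), 4)
    counts, edges = np.histogram(samples, bins=min(nbins, 100000))
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def idealize(trace, unit_current: float, max_levels: int = 5,
             baseline: float | None = None) -> EventList:
    """Half-amplitude multi-level idealization.

    Each sample is assigned level ``round((I - baseline) / unit_current)``
    clipped to [0, max_levels]; runs of equal level become events.
    ``unit_current`` is signed (negative for inward openings).
    """
    if unit_current == 0:
        raise ValueError("unit_current must be nonzero")
    samples = np.asarray(trace.samples, dtype=float)
    if baseline is None:
        baseline = estimate_baseline(trace)
    x = (samples - baseline) / unit_current
    # polarity check: openings should deflect in the direction of unit_current
    if np.sum(x > 0.5) == 0 and np.mean(x < -0.5) > 0.01:
        raise ValueError("unit_current sign inconsistent with trace polarity")
    levels = np.clip(np.floor(x + 0.5).astype(int), 0, max_levels)
    return EventList.from_samples(levels, trace.sampling_interval)


def compute_npo(events: EventList) -> float:
    """NPo = sum over open levels n of n * (time at level n) / total time."""
    if events.total_time <= 0:
        raise ValueError("total_time must be > 0")
    if len(events) == 0:
        raise ValueError("empty event list")
    return events.time_average_level()


def estimate_channel_count(trace, unit_current: float,
                           baseline: float | None = None,
                           prominence_frac: float = 0.01) -> int:
    """Channel count N from peaks of the all-points amplitude histogram.

    Peaks with prominence above ``prominence_frac`` of the histogram maximum
    are mapped to the nearest integer current level; N is the highest level
    seen.  A warning is issued when, under the implied per-channel Po, a
    record of this length would plausibly never visit level N+1.
    """
    samples = np.asarray(trace.samples, dtype=float)
    if baseline is None:
        baseline = estimate_baseline(trace)
    x = (samples - baseline) / unit_current
    nbins = max(int(np.ptp(x) * 20), 10)  # 0.05-level resolution
    counts, edges = np.histogram(x, bins=min(nbins, 50000))
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks, _ = signal.find_peaks(counts, prominence=prominence_frac * counts.max())
    if len(peaks) == 0:
        raise ValueError("no peaks found in amplitude histogram")
    levels = np.unique(np.clip(np.round(centers[peaks]).astype(int), 0, None))
    n = int(levels.max())
    if n == 0:
        raise ValueError("no open-level peak found in amplitude histogram")
    # undercount risk: would an (N+1)-channel patch at the implied per-channel
    # Po plausibly never have visited its top level in a record of this length?
    events = idealize(trace, unit_current, max_levels=max(n + 2, 5), baseline=baseline)
    po_alt = compute_npo(events) / (n + 1)
    if 0.0 < po_alt < 1.0:
        p_top_never = (1.0 - po_alt ** (n + 1)) ** len(events)
        if p_top_never > 0.05:
            warnings.warn(
                f"channel count N={n} may be an underestimate: an extra channel at "
                f"per-channel Po={po_alt:.3g} would go unseen with probability "
                f"{p_top_never:.2g}",
                stacklevel=2,
            )
    return n


def npo_result(trace, unit_current: float, max_levels: int = 5,
               baseline: float | None = None) -> NPoResult:
    """Convenience: idealize, compute NPo, estimate N, and report Po = NPo/N."""
    if baseline is None:
        baseline = estimate_baseline(trace)
    events = idealize(trace, unit_current, max_levels=max_levels, baseline=baseline)
    npo = compute_npo(events)
    n = estimate_channel_count(trace, unit_current, baseline=baseline)
    return NPoResult(NPo=npo, N=n, Po=npo / n, total_time=events.total_time)


def dwell_summary(events: EventList) -> DwellSummary:
    """Open/closed dwell means for a single-channel record.

    The first and last sojourns are censored (their full duration was not
    observed) and are excluded.  Multi-channel records are rejected.
    """
    if events.max_level > 1:
        raise ValueError(
            "dwell_summary requires a single-channel record (max level 1); "
            "multi-channel dwell analysis needs burst analysis, which is not provided"
        )
    levels = events.levels[1:-1]
    durations = events.durations[1:-1]
    open_d = durations[levels == 1]
    closed_d = durations[levels == 0]
    if len(open_d) == 0 or len(closed_d) == 0:
        raise ValueError("need at least one interior open and closed sojourn")
    return DwellSummary(
        mean_open=float(open_d.mean()),
        mean_closed=float(closed_d.mean()),
        sd_open=float(open_d.std(ddof=1)) if len(open_d) > 1 else 0.0,
        sd_closed=float(closed_d.std(ddof=1)) if len(closed_d) > 1 else 0.0,
        n_open_events=len(open_d),
        n_closed_events=len(closed_d),
    )


def fit_exponential_mixture(durations, n_components: int, seed: int = 0) -> MixtureFit:
    """Maximum-likelihood exponential mixture fit of dwell durations via EM."""
    est = ExponentialMixture(n_components=n_components, random_state=seed)
    est.fit(durations)
    return est.result_


@dataclass(frozen=True)
class TitrationRates:
    """Rate constants recovered from dwell means across a ligand titration.

    For the sequential two-open-state chain:
    1/mean_closed = k_on1 * L  and  mean_open = 1/k_off1 + (k_on2/(k_off2*k_off1)) * L,
    so the titration identifies k_on1, k_off1 and the ratio k_on2/k_off2 only.
    """

    k_on1: float
    k_on1_se: float
    k_off1: float
    k_off1_se: float
    k2_ratio: float  # k_on2 / k_off2, per uM
    k2_ratio_se: float


def recover_rates_from_titration(L_values, summaries) -> TitrationRates:
    """Recover (k_on1, k_off1, k_on2/k_off2) from per-concentration dwell means.

    k_on1 comes from a through-origin regression of the opening rate
    (1/mean_closed) on L; k_off1 from the reciprocal intercept of mean open
    time vs L; the ratio from that line's slope times k_off1.
    """
    L = np.asarray(L_values, dtype=float)
    if len(L) < 3 or len(np.unique(L)) < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if np.any(L <= 0):
        raise ValueError("concentrations must be > 0")
    open_means = np.array([s.mean_open for s in summaries], dtype=float)
    closed_means = np.array([s.mean_closed for s in summaries], dtype=float)

    # through-origin OLS: opening rate vs L
    y = 1.0 / closed_means
    k_on1 = float((L @ y) / (L @ L))
    resid = y - k_on1 * L
    dof = max(len(L) - 1, 1)
    k_on1_se = float(np.sqrt((resid @ resid) / dof / (L @ L)))

    res = stats.linregress(L, open_means)
    if res.intercept <= 0:
        raise ValueError("mean-open intercept must be positive to identify k_off1")
    k_off1 = 1.0 / res.intercept
    k_off1_se = res.intercept_stderr / res.intercept ** 2  # delta method
    k2_ratio = res.slope * k_off1
    # first-order propagation, treating slope and intercept as independent
    k2_ratio_se = float(np.hypot(res.stderr * k_off1, res.slope * k_off1_se))
    return TitrationRates(
        k_on1=k_on1, k_on1_se=k_on1_se,
        k_off1=float(k_off1), k_off1_se=float(k_off1_se),
        k2_ratio=float(k2_ratio), k2_ratio_se=k2_ratio_se,
    )
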