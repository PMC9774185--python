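"""Synthetic-data generators with known ground truth.

Everything the analysis pipeline consumes can be generated here: exact
continuous-time Markov state paths, rendered single-channel current traces
(unit current, Gaussian low-pass filtering, additive noise), multi-channel
patches with ground-truth event lists, Hill dose-response tables, GHK
current-voltage tables, and registered two-channel fluorescence image pairs
with a known colocalized fraction of puncta.  Every generator takes an
explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .constants import FARADAY, GAS_CONSTANT_J, GAUSSIAN_SIGMA_FACTOR, ROOM_TEMPERATURE_K
from .fitting import hill_po
from .idealize import EventList
from .kinetics import GatingScheme, generator_matrix, stationary_distribution

__all__ = [
    "StatePath",
    "Trace",
    "IVDataset",
    "DoseResponseDataset",
    "ImagePair",
    "sample_path",
    "ghk_current",
    "reversal_potential",
    "render_trace",
    "simulate_patch",
    "make_dose_response",
    "make_iv_dataset",
    "make_image_pair",
]


@dataclass
class StatePath:
    """Piecewise-constant CTMC trajectory.

    start_times : segment start times (ms), beginning at 0, strictly increasing.
    states : state index per segment (consecutive entries differ).
    total_duration : ms; the final segment ends here.
    """

    start_times: np.ndarray
    states: np.ndarray
    total_duration: float

    def __post_init__(self) -> None:
        self.start_times = np.asarray(self.start_times, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if self.start_times[0] != 0:
            raise ValueError("path must start at t = 0")
        if np.any(np.diff(self.start_times) <= 0):
            raise ValueError("start times must be strictly increasing")
        if self.start_times[-1] >= self.total_duration:
            raise ValueError("last segment must start before total_duration")
        if np.any(np.diff(self.states) == 0):
            raise ValueError("consecutive states must differ")

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """State index at each sample time (ms)."""
        idx = np.searchsorted(self.start_times, t, side="right") - 1
        return self.states[np.clip(idx, 0, len(self.states) - 1)]

    def durations(self) -> np.ndarray:
        bounds = np.append(self.start_times, self.total_duration)
        return np.diff(bounds)

    def occupancy(self, n_states: int) -> np.ndarray:
        """Fraction of time spent in each state."""
        occ = np.bincount(self.states, weights=self.durations(), minlength=n_states)
        return occ / self.total_duration


@dataclass
class Trace:
    """Sampled current record (pA) with generator metadata."""

    sampling_interval: float  # ms
    samples: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sampling_interval

    @property
    def duration(self) -> float:
        return self.samples.size * self.sampling_interval


@dataclass
class IVDataset:
    """Single-channel I-V table with per-point spread."""

    voltages: np.ndarray  # mV
    mean_currents: np.ndarray  # pA
    sd_currents: np.ndarray  # pA
    ion_concentrations: dict  # {"Na_in": mM, "Li_out": mM}
    temperature: float  # K

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if len(np.unique(self.voltages)) != len(self.voltages):
            raise ValueError("voltages must be distinct")
        if any(v <= 0 for v in self.ion_concentrations.values()):
            raise ValueError("ion concentrations must be > 0")


@dataclass
class DoseResponseDataset:
    """Replicated open-probability measurements across ligand concentrations.

    po : array of shape (n_concentrations, n_replicates), clipped to [0, 1].
    """

    concentrations: np.ndarray  # uM
    po: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.po = np.asarray(self.po, dtype=float)
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any((self.po < 0) | (self.po > 1)):
            raise ValueError("Po values must lie in [0, 1]")

    def long_form(self) -> tuple[np.ndarray, np.ndarray]:
        """(L, Po) with one entry per replicate observation."""
        n_rep = self.po.shape[1]
        return np.repeat(self.concentrations, n_rep), self.po.ravel()


@dataclass
class ImagePair:
    """Registered two-channel 16-bit image pair with generation ground truth."""

    channel1: np.ndarray
    channel2: np.ndarray
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.channel1.shape != self.channel2.shape:
            raise ValueError("channels must have identical shapes")
        for ch in (self.channel1, self.channel2):
            if ch.min() < 0 or ch.max() > 65535:
                raise ValueError("intensities must fit the 16-bit range")


def sample_path(scheme: GatingScheme, L: float, duration_ms: float, seed,
                start: str = "stationary") -> StatePath:
    """Exact CTMC simulation: exponential holding times, rate-proportional jumps.

    The initial state is drawn from the stationary distribution at L
    (steady-state recordings) or forced to the first closed state with
    ``start='closed'`` (excision-style protocols).  At L = 0 the closed state
    is absorbing and the path is a single everlasting closed sojourn.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    Q = generator_matrix(scheme, L)
    exit_rates = -np.diag(Q)
    if start == "closed":
        state = int(np.argmax(~scheme.open_mask))
    elif start == "stationary":
        if L == 0:
            state = int(np.argmax(~scheme.open_mask))
        else:
            state = int(rng.choice(scheme.n_states, p=stationary_distribution(scheme, L)))
    else:
        raise ValueError(f"unknown start {start!r}")
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        rate = exit_rates[state]
        if rate <= 0:  # absorbing (L = 0)
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration_ms:
            break
        p = Q[state].copy()
        p[state] = 0.0
        state = int(rng.choice(scheme.n_states, p=p / p.sum()))
        times.append(t)
        states.append(state)
    return StatePath(start_times=np.array(times), states=np.array(states),
                     total_duration=duration_ms)


def ghk_current(V, p_na: float, p_li: float, na_in: float = 3.0, li_out: float = 140.0,
                T: float = ROOM_TEMPERATURE_K):
    """Constant-field (GHK) current (pA) for internal Na+ and external Li+.

    ``p_na`` and ``p_li`` are absolute permeability scales in pA/mM (the GHK
    prefactor folded in); V is membrane potential in mV and inward current is
    negative.  V = 0 is evaluated by its analytic limit.
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    if na_in < 0 or li_out < 0:
        raise ValueError("concentrations must be >= 0")
    V = np.asarray(V, dtype=float)
    u = V * 1e-3 * FARADAY / (GAS_CONSTANT_J * T)

    def g(x):
        x = np.asarray(x, dtype=float)
        out = np.ones_like(x)
        nz = np.abs(x) > 1e-9
        out[nz] = x[nz] / (-np.expm1(-x[nz]))
        return out

    result = p_na * na_in * g(u) - p_li * li_out * g(-u)
    return float(result) if np.isscalar(V) or V.ndim == 0 else result


def reversal_potential(perm_ratio: float, na_in: float = 3.0, li_out: float = 140.0,
                       T: float = ROOM_TEMPERATURE_K) -> float:
    """Zero-current voltage (mV): Erev = (RT/F) ln(P_Li [Li]_out / (P_Na [Na]_in))."""
    return float(GAS_CONSTANT_J * T / FARADAY * 1e3 * np.log(perm_ratio * li_out / na_in))


def render_trace(paths, open_mask, unit_current: float, noise_sd: float,
                 filter_cutoff: float | None, sampling_rate: float, seed,
                 metadata: dict | None = None) -> Trace:
    """Render state paths into a sampled, filtered, noisy current trace.

    Ideal current is ``unit_current`` times the number of channels in an
    open-class state; it is sampled at ``sampling_rate`` (Hz), low-pass
    filtered with a Gaussian response (-3 dB at ``filter_cutoff`` Hz, which
    imposes the half-amplitude dead time 0.179/f_c), and white Gaussian noise
    of ``noise_sd`` pA is added after filtering.
    """
    if filter_cutoff is not None and sampling_rate < 4 * filter_cutoff:
        raise ValueError("sampling_rate must be >= 4x filter_cutoff")
    paths = list(paths)
    open_mask = np.asarray(open_mask, dtype=bool)
    dt_ms = 1e3 / sampling_rate
    duration = min(p.total_duration for p in paths)
    n = int(np.floor(duration / dt_ms))
    t = (np.arange(n) + 0.5) * dt_ms  # sample at interval midpoints
    level = np.zeros(n, dtype=int)
    for p in paths:
        level += open_mask[p.state_at(t)]
    ideal = unit_current * level.astype(float)
    if filter_cutoff is not None:
        sigma_ms = GAUSSIAN_SIGMA_FACTOR / filter_cutoff * 1e3
        ideal = ndimage.gaussian_filter1d(ideal, sigma_ms / dt_ms, mode="nearest")
    rng = np.random.default_rng(seed)
    samples = ideal + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else ideal
    meta = {
        "n_channels": len(paths), "unit_current": unit_current, "noise_sd": noise_sd,
        "filter_cutoff": filter_cutoff, "sampling_rate": sampling_rate, "seed": seed,
    }
    if metadata:
        meta.update(metadata)
    return Trace(sampling_interval=dt_ms, samples=samples, metadata=meta)


def _paths_to_events(paths, open_mask) -> EventList:
    """Ground-truth superposition level function as an EventList."""
    open_mask = np.asarray(open_mask, dtype=bool)
    duration = min(p.total_duration for p in paths)
    cuts = np.unique(np.concatenate([p.start_times for p in paths] + [[0.0, duration]]))
    cuts = cuts[cuts < duration]
    mids = (cuts + np.append(cuts[1:], duration)) / 2.0
    level = np.zeros(len(cuts), dtype=int)
    for p in paths:
        level += open_mask[p.state_at(mids)]
    keep = np.concatenate([[True], np.diff(level) != 0])
    starts = cuts[keep]
    levels = level[keep]
    durations = np.diff(np.append(starts, duration))
    return EventList(levels=levels, starts=starts, durations=durations, total_time=duration)


def simulate_patch(n_channels: int, scheme: GatingScheme, L: float, duration_ms: float,
                   unit_current: float = 0.5, noise_sd: float = 0.15,
                   filter_cutoff: float | None = 100.0, sampling_rate: float = 4000.0,
                   seed=0, start: str = "stationary") -> tuple[Trace, EventList]:
    """Simulate a patch of independent identical channels.

    Returns the rendered trace and the ground-truth event list of the
    superposition level function (number of open channels over time).
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_channels + 1)
    paths = [sample_path(scheme, L, duration_ms, child[i], start=start)
             for i in range(n_channels)]
    trace = render_trace(paths, scheme.open_mask, unit_current, noise_sd,
                         filter_cutoff, sampling_rate, child[-1],
                         metadata={"L": L, "seed": seed})
    return trace, _paths_to_events(paths, scheme.open_mask)


def make_dose_response(pmax: float, k05: float, n_hill: float, concentrations,
                       replicates: int = 11, noise_sd: float = 0.02,
                       seed=0) -> DoseResponseDataset:
    """Hill-model Po table with additive Gaussian noise, clipped to [0, 1]."""
    if not (0 < pmax <= 1):
        raise ValueError("pmax must be in (0, 1]")
    if k05 <= 0 or n_hill <= 0:
        raise ValueError("k05 and n_hill must be > 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    L = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    mean = hill_po(L, pmax, k05, n_hill)
    po = mean[:, None] + rng.normal(0.0, noise_sd, size=(L.size, replicates))
    return DoseResponseDataset(concentrations=L, po=np.clip(po, 0.0, 1.0))


def make_iv_dataset(p_na: float, p_li: float, voltages, na_in: float = 3.0,
                    li_out: float = 140.0, T: float = ROOM_TEMPERATURE_K,
                    noise_sd: float = 0.05, seed=0) -> IVDataset:
    """GHK-model I-V table with additive Gaussian noise."""
    V = np.asarray(voltages, dtype=float)
    if V.size < 4:
        raise ValueError("need >= 4 voltages")
    rng = np.random.default_rng(seed)
    mean = ghk_current(V, p_na, p_li, na_in, li_out, T)
    currents = mean + rng.normal(0.0, noise_sd, size=V.size)
    return IVDataset(voltages=V, mean_currents=currents,
                     sd_currents=np.full(V.size, noise_sd),
                     ion_concentrations={"Na_in": na_in, "Li_out": li_out}, temperature=T)


def make_image_pair(shape=(128, 128), n_puncta: int = 60, colocalized_fraction: float = 0.5,
                    psf_sigma: float = 1.5, background: float = 200.0,
                    noise_sd: float = 30.0, amplitude: float = 8000.0,
                    seed=0) -> ImagePair:
    """Two-channel puncta image pair with a known colocalized fraction.

    Puncta are Gaussian spots of width ``psf_sigma`` px.  A fraction of spot
    coordinates is shared between channels; the rest are channel-exclusive and
    placed at least ``4 * psf_sigma`` away from every other punctum, so at
    fraction 0 the two spot sets are disjoint and non-overlapping by
    construction.  Photon noise is approximated as additive Gaussian on top of
    a uniform background; output is clipped to uint16.
    """
    if not (0.0 <= colocalized_fraction <= 1.0):
        raise ValueError("colocalized_fraction must be in [0, 1]")
    n_pix = shape[0] * shape[1]
    n_shared = int(round(colocalized_fraction * n_puncta))
    n_total = 2 * n_puncta - n_shared
    if n_total > n_pix:
        raise ValueError("puncta count exceeds pixel count")
    rng = np.random.default_rng(seed)
    min_sep = 4.0 * psf_sigma
    coords: list[tuple[int, int]] = []
    attempts = 0
    while len(coords) < n_total:
        cand = (int(rng.integers(shape[0])), int(rng.integers(shape[1])))
        attempts += 1
        if attempts > 1000 * n_total:
            raise ValueError("could not place puncta at the requested density")
        if all((cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 >= min_sep**2 for c in coords):
            coords.append(cand)
    coords = np.array(coords)
    shared = coords[:n_shared]
    only1 = coords[n_shared:n_puncta]
    only2 = coords[n_puncta:]

    def render(spots):
        img = np.zeros(shape, dtype=float)
        if len(spots):
            img[spots[:, 0], spots[:, 1]] = 1.0
            img = ndimage.gaussian_filter(img, psf_sigma, mode="constant")
            img *= 2 * np.pi * psf_sigma**2  # unit peak height per spot
        return amplitude * img

    ch1 = render(np.vstack([shared, only1])) + background
    ch2 = render(np.vstack([shared, only2])) + background
    if noise_sd > 0:
        ch1 = ch1 + rng.normal(0.0, noise_sd, size=shape)
        ch2 = ch2 + rng.normal(0.0, noise_sd, size=shape)
    truth = {
        "n_puncta_1": n_puncta, "n_puncta_2": n_puncta,
        "colocalized_fraction": colocalized_fraction, "psf_sigma": psf_sigma,
        "background": background, "noise_sd": noise_sd, "seed": seed,
    }
    to_u16 = lambda a: np.clip(np.round(a), 0, 65535).astype(np.uint16)
    return ImagePair(channel1=to_u16(ch1), channel2=to_u16(ch2), ground_truth=truth)
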