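"""Estimator-recovery experiments.

Each experiment generates synthetic data from published single-channel
parameter estimates used as generative truth, runs the package's estimator on
the synthetic data, and reports the estimate, its standard error, the
generative truth, and the problem size.  They are the computational backbone
of the acceptance checks and are also usable as worked examples.

Generative conditions (fixed study conditions, not tuning knobs):

* dose-response: Hill parameters Pmax = 0.411, K0.5 = 22 uM, n = 2.5;
  concentrations {0, 10, 20, 30, 50} uM, 11 replicates, noise sd 0.02.
* I-V: reversal potential 83 mV and slope conductance 6.6 pS over
  [-120, -40] mV for 3 mM internal Na+ / 140 mM external Li+ at 295.15 K;
  ten voltages from -120 to +60 mV, noise sd 0.05 pA.
* dwell times: two-state gating with mean open time 41.1 ms (the MLP-1
  knockout phenotype) and mean closed time 60 ms at 20 uM ligand.
* open probability: two-state gating at the wild-type Po of 0.236.
* opening-rate titration: slope 7.97e-6 /ms/uM with the printed standard
  error (1.63e-6) as the per-point noise scale.
"""

from __future__ import annotations

import numpy as np

from . import synth
from .fitting import GHKCurve, HillCurve, linear_rate_fit
from .idealize import dwell_summary, idealize, npo_result
from .kinetics import two_state_scheme

__all__ = [
    "hill_recovery",
    "ghk_recovery",
    "rate_slope_recovery",
    "dwell_time_recovery",
    "open_probability_recovery",
]

HILL_TRUTH = {"pmax": 0.411, "k05": 22.0, "n": 2.5}
HILL_CONCENTRATIONS = (0.0, 10.0, 20.0, 30.0, 50.0)
HILL_REPLICATES = 11
HILL_NOISE_SD = 0.02

IV_EREV_MV = 83.0
IV_CONDUCTANCE_PS = 6.6
IV_TEMPERATURE_K = 295.15
IV_NA_IN_MM = 3.0
IV_LI_OUT_MM = 140.0
IV_NOISE_SD_PA = 0.05

KO_MEAN_OPEN_MS = 41.1
WT_PO = 0.236

RATE_SLOPE_PER_MS_UM = 7.97e-6
RATE_SLOPE_SE = 1.63e-6


def hill_recovery(seed: int = 0) -> dict:
    """Generate a dose-response table from the Hill truth and refit it."""
    data = synth.make_dose_response(
        HILL_TRUTH["pmax"], HILL_TRUTH["k05"], HILL_TRUTH["n"],
        HILL_CONCENTRATIONS, replicates=HILL_REPLICATES,
        noise_sd=HILL_NOISE_SD, seed=seed)
    L, po = data.long_form()
    fit = HillCurve().fit(L, po)
    return {
        "k05": fit.k05_, "k05_se": float(fit.se_[1]), "k05_true": HILL_TRUTH["k05"],
        "pmax": fit.pmax_, "pmax_se": float(fit.se_[0]), "pmax_true": HILL_TRUTH["pmax"],
        "n_hill": fit.n_, "n_hill_se": float(fit.se_[2]), "n_hill_true": HILL_TRUTH["n"],
        "r_squared": fit.r_squared_, "n_obs": int(L.size),
    }


def _generative_ghk_params() -> tuple[float, float]:
    """(p_na, p_li) in pA/mM reproducing the target Erev and conductance.

    The permeability ratio is fixed by the reversal potential; the absolute
    scale is calibrated so the noiseless curve's least-squares slope over
    [-120, -40] mV equals the target conductance.
    """
    from .constants import FARADAY, GAS_CONSTANT_J
    rt_f = GAS_CONSTANT_J * IV_TEMPERATURE_K / FARADAY * 1e3  # mV
    ratio = np.exp(IV_EREV_MV / rt_f) * IV_NA_IN_MM / IV_LI_OUT_MM
    grid = np.arange(-120.0, -39.5, 1.0)
    cur = synth.ghk_current(grid, 1.0, ratio, IV_NA_IN_MM, IV_LI_OUT_MM, IV_TEMPERATURE_K)
    unit_slope_ps = np.polyfit(grid, cur, 1)[0] * 1e3
    p_na = IV_CONDUCTANCE_PS / unit_slope_ps
    return p_na, p_na * ratio


def ghk_recovery(seed: int = 0) -> dict:
    """Simulate a ten-voltage I-V from the GHK truth and refit it."""
    p_na, p_li = _generative_ghk_params()
    voltages = np.linspace(-120.0, 60.0, 10)
    data = synth.make_iv_dataset(p_na, p_li, voltages, IV_NA_IN_MM, IV_LI_OUT_MM,
                                 IV_TEMPERATURE_K, noise_sd=IV_NOISE_SD_PA, seed=seed)
    fit = GHKCurve(c_in=IV_NA_IN_MM, c_out=IV_LI_OUT_MM,
                   temperature=IV_TEMPERATURE_K).fit(data.voltages, data.mean_currents)
    g, g_se = fit.slope_conductance(-120.0, -40.0, with_se=True)
    return {
        "erev": fit.erev_, "erev_se": fit.erev_se_, "erev_true": IV_EREV_MV,
        "conductance": g, "conductance_se": g_se, "conductance_true": IV_CONDUCTANCE_PS,
        "perm_ratio": fit.perm_ratio_, "n_obs": int(voltages.size),
    }


def rate_slope_recovery(seed: int = 0) -> dict:
    """Regenerate the opening-rate-vs-concentration line and refit its slope.

    The per-point noise sd is the printed slope standard error scaled back to
    an observation sd through the design (se = sd / sqrt(sum dev^2)).
    """
    L = np.asarray(HILL_CONCENTRATIONS)
    point_sd = RATE_SLOPE_SE * np.sqrt(np.sum((L - L.mean()) ** 2))
    rng = np.random.default_rng(seed)
    rates = RATE_SLOPE_PER_MS_UM * L + rng.normal(0.0, point_sd, size=L.size)
    fit = linear_rate_fit(L, rates)
    return {
        "slope": fit.slope, "slope_se": fit.slope_se,
        "slope_true": RATE_SLOPE_PER_MS_UM, "p_value": fit.p_value,
        "n_obs": int(L.size),
    }


def dwell_time_recovery(seed: int = 0, duration_ms: float = 230_000.0) -> dict:
    """Recover the knockout mean open time from an idealized simulated patch.

    Two-state gating with closing rate 1/41.1 per ms and mean closed time
    60 ms at 20 uM ligand, rendered at 4000 Hz with a wide (1 kHz) bandwidth
    and 0.05 pA noise on a 0.5 pA unit current, idealized at half amplitude.
    """
    L = 20.0
    mean_closed = 60.0
    scheme = two_state_scheme(k_on=1.0 / (mean_closed * L), k_off=1.0 / KO_MEAN_OPEN_MS)
    trace, _ = synth.simulate_patch(
        1, scheme, L, duration_ms, unit_current=0.5, noise_sd=0.05,
        filter_cutoff=1000.0, sampling_rate=4000.0, seed=seed)
    events = idealize(trace, unit_current=0.5, max_levels=1)
    summary = dwell_summary(events)
    return {
        "mean_open": summary.mean_open,
        "mean_open_se": summary.sd_open / np.sqrt(summary.n_open_events),
        "mean_open_true": KO_MEAN_OPEN_MS,
        "n_open_events": summary.n_open_events,
    }


def open_probability_recovery(seed: int = 0, duration_ms: float = 600_000.0) -> dict:
    """Recover the wild-type Po via the NPo statistic on a simulated patch.

    Two-state rates are chosen so the stationary open probability equals the
    wild-type value (mean open time 100 ms); a single channel is simulated for
    ten minutes of model time and Po = NPo / N with N from the amplitude
    histogram.  The Monte-Carlo standard error comes from 20 block means of
    the idealized level function.
    """
    L = 20.0
    k_off = 0.01
    k_on = k_off * WT_PO / (1.0 - WT_PO) / L
    scheme = two_state_scheme(k_on=k_on, k_off=k_off)
    trace, _ = synth.simulate_patch(
        1, scheme, L, duration_ms, unit_current=0.5, noise_sd=0.05,
        filter_cutoff=1000.0, sampling_rate=4000.0, seed=seed)
    result = npo_result(trace, unit_current=0.5)
    # block-means standard error of the time-averaged level
    events = idealize(trace, unit_current=0.5, max_levels=result.N)
    counts = np.round(events.durations / trace.sampling_interval).astype(int)
    level_samples = np.repeat(events.levels, counts)
    n_blocks = 20
    blocks = np.array_split(level_samples, n_blocks)
    block_means = np.array([b.mean() for b in blocks])
    se = float(block_means.std(ddof=1) / np.sqrt(n_blocks)) / result.N
    return {
        "po": result.Po, "po_se": se, "po_true": WT_PO,
        "npo": result.NPo, "n_channels": result.N,
        "duration_s": duration_ms / 1e3,
    }
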