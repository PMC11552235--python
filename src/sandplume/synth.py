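"""Seeded generators for nerve traces, dose–response series, and behavioural trials.

The trace generator is spike-based rather than envelope-based: multi-unit
activity is an inhomogeneous Poisson train of biphasic ~2 ms waveforms on
Gaussian instrument noise, so the downstream rectify-and-filter stage is
genuinely exercised.  Firing rate above spontaneous follows a steep Hill
gain in dose (half-activation at the species' detection threshold for the
compound, with a mild logarithmic supra-threshold creep so response areas
keep growing past saturation, as recruitment does in multi-unit data) times
a kinetics envelope: appetitive tastants drive a fast transient burst, TRP
agonists a slow sustained rise.

Each trace stores its own deterministic ground truth in ``meta``: the
expected rectified-envelope response area given the drawn spike times
(exact Gaussian-rectification expectation), against which the quantifier
can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import erf
from scipy.stats import binomtest

from .capsule import DetectabilityResult
from .nerve import GAUSS_SIGMA_S, DoseResponseSeries, NerveTrace, quantify

__all__ = [
    "SpeciesProfile",
    "digging_profile",
    "non_digging_profile",
    "DEFAULT_DOSES",
    "gen_trace",
    "gen_dose_response",
    "gen_trials",
    "summarize_trials",
]

# trace design (seconds) shared by generator and quantifier defaults
STIM_ONSET = 30.0
STIM_OFFSET = 50.0
PRE_WINDOW = 10.0
TAIL = 30.0

# generator constants
NOISE_SD = 2.0e-5          # instrument noise, V (20 uV RMS)
SPONTANEOUS_RATE = 2.0     # Hz
MAX_RATE = 100.0           # Hz of evoked multi-unit firing at saturation
HILL_N = 4.0               # steepness of the dose gain
SPIKE_MS = 2.0             # biphasic waveform duration

#: Default dose grid for dose–response designs: 7 log-spaced doses from
#: 10 uM to 10 mM (half-decade steps), bracketing both species' thresholds.
DEFAULT_DOSES = np.geomspace(0.01, 10.0, 7)   # mol/m^3


@dataclass(frozen=True)
class SpeciesProfile:
    """Detection thresholds (mol/m^3) and response kinetics per compound."""

    name: str
    threshold_map: dict
    kinetics_map: dict

    def __post_init__(self) -> None:
        if not self.threshold_map or not self.kinetics_map:
            raise ValueError("threshold_map and kinetics_map must be non-empty")
        if any(v <= 0 for v in self.threshold_map.values()):
            raise ValueError("thresholds must be positive")


def digging_profile() -> SpeciesProfile:
    """Digging species: L-amino-acid threshold 100 uM; betaine-sensitive."""
    return SpeciesProfile(
        name="digging",
        threshold_map={"l-amino-acids": 0.1, "betaine": 0.1, "carvacrol": 0.1},
        kinetics_map={
            "l-amino-acids": "fast_transient",
            "betaine": "fast_transient",
            "carvacrol": "slow_sustained",
        },
    )


def non_digging_profile() -> SpeciesProfile:
    """Non-digging species: 100x less sensitive to L-amino acids (10 mM)."""
    return SpeciesProfile(
        name="non-digging",
        threshold_map={"l-amino-acids": 10.0, "betaine": 0.1, "carvacrol": 0.1},
        kinetics_map={
            "l-amino-acids": "fast_transient",
            "betaine": "fast_transient",
            "carvacrol": "slow_sustained",
        },
    )


def _dose_gain(dose: float, threshold: float) -> float:
    """Hill activation with half-point at the threshold, plus mild log creep."""
    if dose <= 0:
        return 0.0
    h = dose**HILL_N / (dose**HILL_N + threshold**HILL_N)
    return h * (1.0 + 0.1 * np.log10(1.0 + dose / threshold))


def _kinetics_envelope(tau: np.ndarray, kind: str, stim_dur: float) -> np.ndarray:
    """Peak-normalised firing-rate envelope, tau in seconds since stimulus onset."""
    env = np.zeros_like(tau)
    pos = tau >= 0
    tp = tau[pos]
    if kind == "fast_transient":
        raw = (1.0 - np.exp(-tp / 1.0)) * np.exp(-tp / 3.0)
        peak = 0.4724703937   # max of (1-e^-tau) e^(-tau/3), at tau = ln 4
        env[pos] = raw / peak
    elif kind == "slow_sustained":
        rise = 1.0 - np.exp(-np.minimum(tp, stim_dur) / 8.0)
        decay = np.exp(-np.clip(tp - stim_dur, 0.0, None) / 100.0)
        raw = rise * decay
        env[pos] = raw / (1.0 - np.exp(-stim_dur / 8.0))
    else:
        raise ValueError(f"unknown kinetics {kind!r}")
    return env


def _expected_rectified(s: np.ndarray, sigma: float) -> np.ndarray:
    """E|s + n| for n ~ N(0, sigma^2): exact folded-normal mean."""
    return s * erf(s / (sigma * np.sqrt(2.0))) + sigma * np.sqrt(2.0 / np.pi) * np.exp(
        -(s**2) / (2.0 * sigma**2)
    )


def gen_trace(profile: SpeciesProfile, compound: str, dose: float,
              duration: float = 90.0, fs: float = 10_000.0, snr: float = 5.0,
              seed: int | np.random.SeedSequence = 0,
              onset: float = STIM_ONSET, offset: float = STIM_OFFSET) -> NerveTrace:
    """Synthesise one stimulated multi-unit nerve recording.

    ``snr`` is the spike amplitude over the noise RMS.  ``meta`` records the
    dose, the true kinetics label, and ``gt_area`` — the expected quantified
    response area for the drawn spike train (folded-normal expectation of the
    rectified signal, passed through the same filter/baseline/integration as
    the quantifier).
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if fs < 1000.0:
        raise ValueError("fs must be >= 1000 Hz to carry 2 ms spike waveforms")
    if duration < 60.0:
        raise ValueError("duration must be >= 60 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    tgrid = np.arange(n) / fs

    kind = profile.kinetics_map.get(compound, "fast_transient")
    threshold = profile.threshold_map.get(compound)
    gain = _dose_gain(dose, threshold) if threshold is not None else 0.0
    rate = SPONTANEOUS_RATE + MAX_RATE * gain * _kinetics_envelope(
        tgrid - onset, kind, offset - onset
    )

    # inhomogeneous Poisson spike times by inverse-CDF sampling
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) / fs)])
    n_spikes = rng.poisson(cum[-1])
    spike_t = np.sort(np.interp(rng.uniform(0.0, cum[-1], n_spikes), cum, tgrid))

    # biphasic waveform: one sine cycle over SPIKE_MS
    wf_len = max(int(round(SPIKE_MS / 1000.0 * fs)), 2)
    wf = np.sin(2.0 * np.pi * np.arange(wf_len) / wf_len)
    amp = snr * NOISE_SD * rng.uniform(0.7, 1.3, n_spikes)

    spikes = np.zeros(n)
    idx = np.round(spike_t * fs).astype(int)
    for i, a in zip(idx, amp):
        hi = min(i + wf_len, n)
        spikes[i:hi] += a * wf[: hi - i]

    samples = spikes + rng.normal(0.0, NOISE_SD, n)

    # Deterministic ground truth for the quantifier, given the drawn spikes:
    # the expected envelope is the filtered folded-normal mean, and the
    # expected *clipped* excess additionally carries the half-rectification
    # bias of the envelope's own noise (E max(X,0) for X ~ N(m, sd^2)),
    # with sd from the filter's variance-reduction factor sum(g^2).
    from scipy.special import ndtr

    sig_samples = GAUSS_SIGMA_S * fs
    mu_point = _expected_rectified(spikes, NOISE_SD)
    mu = gaussian_filter1d(mu_point, sig_samples, mode="reflect")
    var_point = spikes**2 + NOISE_SD**2 - mu_point**2
    var_env = gaussian_filter1d(var_point, sig_samples / np.sqrt(2.0),
                                mode="reflect") / (2.0 * np.sqrt(np.pi) * sig_samples)
    sd_env = np.sqrt(np.clip(var_env, 0.0, None))
    i_on = int(round(onset * fs))
    i_pre = int(round((onset - PRE_WINDOW) * fs))
    i_end = min(int(round((offset + TAIL) * fs)), n - 1)
    gt_base = float(mu[i_pre:i_on].mean())
    m = mu[i_on:i_end + 1] - gt_base
    sd = sd_env[i_on:i_end + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, m / np.where(sd > 0, sd, 1.0), np.sign(m) * np.inf)
    expected_excess = m * ndtr(z) + sd * np.exp(-0.5 * np.clip(z, -37, 37) ** 2) / np.sqrt(2 * np.pi)
    gt_area = float(np.trapezoid(expected_excess, dx=1.0 / fs))

    return NerveTrace(
        fs=fs,
        samples=samples,
        stimuli=[("stim", onset, offset)],
        species=profile.name,
        meta={
            "compound": compound,
            "dose": dose,
            "kinetics_true": kind if gain > 0 else "none",
            "gt_area": gt_area,
            "snr": snr,
            "n_spikes": int(n_spikes),
        },
    )


def gen_dose_response(profile: SpeciesProfile, compound: str = "l-amino-acids",
                      doses=None, n_reps: int = 4, n_blanks: int = 8,
                      seed: int = 0, fs: float = 10_000.0) -> DoseResponseSeries:
    """Generate traces over a dose grid (plus blanks) and quantify each.

    Defaults emulate the published design: 4 replicate legs per dose over
    ``DEFAULT_DOSES``; blanks are zero-dose traces quantified with the same
    window.  The blank pool is larger (8) than the per-dose replication:
    the detection rule keys on SD(blanks), and a 4-sample SD is unstable
    enough to let blank-level doses slip over the criterion.
    """
    doses = DEFAULT_DOSES if doses is None else np.asarray(doses, dtype=float)
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly ascending")
    children = np.random.SeedSequence(seed).spawn(len(doses) * n_reps + n_blanks)
    it = iter(children)
    blanks = np.array([
        quantify(gen_trace(profile, compound, 0.0, fs=fs, seed=next(it)), "stim",
                 pre_window=PRE_WINDOW, tail=TAIL).area
        for _ in range(n_blanks)
    ])
    responses = []
    for dose in doses:
        responses.append(np.array([
            quantify(gen_trace(profile, compound, float(dose), fs=fs, seed=next(it)),
                     "stim", pre_window=PRE_WINDOW, tail=TAIL).area
            for _ in range(n_reps)
        ]))
    return DoseResponseSeries(compound=compound, species=profile.name,
                              doses=doses, responses=responses, blanks=blanks)


def gen_trials(params_grid, model_results: list[DetectabilityResult],
               encounter_prob: float = 0.8, n_trials: int = 10, seed: int = 0,
               false_rate: float = 0.0, species: str = "digging",
               label: str = "capsule") -> pd.DataFrame:
    """Bernoulli behavioural trials driven by model detectability.

    ``params_grid`` is a list of (c0, depth) pairs that must match the
    corresponding DetectabilityResult entries.  Success probability is
    ``encounter_prob`` when the condition is detectable, ``false_rate``
    (default 0: controls are never found) otherwise.
    """
    if not (0.0 < encounter_prob <= 1.0):
        raise ValueError("encounter_prob must be in (0, 1]")
    params_grid = list(params_grid)
    if len(params_grid) != len(model_results):
        raise ValueError("params_grid and model_results length mismatch")
    for (c0, depth), res in zip(params_grid, model_results):
        if not (np.isclose(c0, res.c0) and np.isclose(depth, res.depth_l)):
            raise ValueError(
                f"grid condition (c0={c0}, depth={depth}) does not match model "
                f"result (c0={res.c0}, depth={res.depth_l})"
            )
    rng = np.random.default_rng(seed)
    rows = []
    for (c0, depth), res in zip(params_grid, model_results):
        p = encounter_prob if res.detected_within_t_max else false_rate
        outcomes = rng.random(n_trials) < p
        for k, success in enumerate(outcomes):
            rows.append({
                "species": species, "label": label, "c0": c0, "depth": depth,
                "success": int(success), "trial_id": k, "seed": seed,
            })
    return pd.DataFrame(rows)


def summarize_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition success rates with exact (Clopper–Pearson) 95% CIs."""
    if table.empty:
        raise ValueError("empty trial table")
    out = []
    for (c0, depth), grp in table.groupby(["c0", "depth"], sort=True):
        k = int(grp["success"].sum())
        n = len(grp)
        ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
        out.append({
            "c0": c0, "depth": depth, "n": n, "successes": k, "rate": k / n,
            "ci_low": float(ci.low), "ci_high": float(ci.high),
        })
    return pd.DataFrame(out)
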