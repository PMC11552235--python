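"""Quantification of extracellular leg-nerve recordings and dose–response thresholds.

The recording pipeline mirrors standard multi-unit practice: rectify the
signal, smooth with a 25 Hz low-pass Gaussian to obtain a response envelope,
subtract the pre-stimulus baseline, and integrate the (rectified) excess over
the response window.  Response kinetics separate appetitive tastants
(fast, transient multi-unit bursts) from chemesthetic TRP-channel agonists
(slow, sustained firing).  Detection thresholds from dose–response series use
a blank-referenced rule: the lowest dose whose mean response area exceeds the
blank mean by three blank standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "GAUSS_SIGMA_S",
    "NerveTrace",
    "ResponseQuant",
    "DoseResponseSeries",
    "envelope",
    "quantify",
    "classify_kinetics",
    "estimate_threshold",
    "response_heatmap",
]

#: Time-domain sigma of the 25 Hz low-pass Gaussian.  The filter is
#: parameterised by its -3 dB point: |H(f)| = exp(-2 pi^2 sigma^2 f^2) equals
#: 1/sqrt(2) at f = 25 Hz when sigma = sqrt(ln 2) / (2 pi * 25) ~= 5.30 ms.
GAUSS_SIGMA_S = float(np.sqrt(np.log(2.0)) / (2.0 * np.pi * 25.0))


@dataclass
class NerveTrace:
    """Sampled extracellular voltage with stimulus-window annotations.

    ``stimuli`` is a list of ``(label, onset_s, offset_s)`` tuples; onsets must
    be sorted and windows must fit inside the trace.
    """

    fs: float
    samples: np.ndarray
    stimuli: list[tuple[str, float, float]]
    species: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        dur = self.duration
        onsets = [s[1] for s in self.stimuli]
        if onsets != sorted(onsets):
            raise ValueError("stimulus onsets must be sorted")
        for label, onset, offset in self.stimuli:
            if not (0.0 <= onset < offset <= dur):
                raise ValueError(f"stimulus {label!r} window [{onset}, {offset}] outside trace")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class ResponseQuant:
    """Quantified response to one stimulus window."""

    stimulus: str
    baseline: float            # mean pre-stimulus envelope, V
    area: float                # integrated baseline-subtracted envelope, V*s
    peak: float                # peak envelope excess, V
    time_to_peak: float        # s after stimulus onset
    decay_fraction: float      # envelope excess at window end / peak
    kinetics_class: str        # fast_transient | slow_sustained | none
    baseline_sd: float = 0.0   # envelope SD over the baseline window, V


@dataclass
class DoseResponseSeries:
    """Replicate response areas per dose, plus blank (zero-dose) controls.

    Doses in mol/m^3, ascending; ``responses[i]`` are the replicate areas at
    ``doses[i]``; ``blanks`` are replicate areas with no stimulus compound.
    """

    compound: str
    species: str
    doses: np.ndarray
    responses: list[np.ndarray]
    blanks: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.blanks = np.asarray(self.blanks, dtype=float)
        self.responses = [np.asarray(r, dtype=float) for r in self.responses]
        if len(self.doses) < 2:
            raise ValueError("need at least two doses")
        if len(self.responses) != len(self.doses):
            raise ValueError("responses must align with doses")
        if self.blanks.size < 1:
            raise ValueError("need at least one blank replicate")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for dose, reps in [(0.0, self.blanks)] + list(zip(self.doses, self.responses)):
            for i, area in enumerate(np.atleast_1d(reps)):
                rows.append(
                    {"compound": self.compound, "species": self.species,
                     "dose_molar": dose / 1e3, "replicate": i, "area": area}
                )
        return pd.DataFrame(rows)


def envelope(trace: NerveTrace) -> np.ndarray:
    """Rectified, 25 Hz Gaussian low-passed response envelope.

    Zero-phase by construction (symmetric kernel), reflected at the edges.
    """
    if trace.fs < 100.0:
        raise ValueError("fs must be >= 100 Hz to resolve a 25 Hz envelope")
    sigma_samples = GAUSS_SIGMA_S * trace.fs
    if len(trace.samples) < 6 * sigma_samples:
        raise ValueError("trace shorter than 6 filter sigmas")
    return gaussian_filter1d(np.abs(trace.samples), sigma_samples, mode="reflect")


def _find_stimulus(trace: NerveTrace, label: str) -> tuple[float, float]:
    for lab, onset, offset in trace.stimuli:
        if lab == label:
            return onset, offset
    raise KeyError(f"stimulus {label!r} not found in trace (have "
                   f"{[s[0] for s in trace.stimuli]})")


def quantify(trace: NerveTrace, stimulus_label: str, pre_window: float = 10.0,
             tail: float = 30.0, env: np.ndarray | None = None,
             kin_smooth: float = 1.0, **classify_kwargs) -> ResponseQuant:
    """Baseline-subtracted response area, peak, and kinetics for one stimulus.

    The baseline is the mean envelope over ``pre_window`` seconds before
    stimulus onset (at least 5 s must exist).  The response window runs from
    onset to offset + ``tail`` (clipped to the trace end); the area is the
    trapezoidal integral of ``max(envelope - baseline, 0)`` over it.  Blanks
    are quantified with the same window lengths.

    Peak, time-to-peak and decay fraction describe response *kinetics*, which
    live on second timescales; they are read off the excess envelope after an
    additional Gaussian smoothing of ``kin_smooth`` seconds (0 disables) so
    that individual multi-unit spike bumps do not masquerade as the peak.
    """
    onset, offset = _find_stimulus(trace, stimulus_label)
    if onset < 5.0:
        raise ValueError("need a pre-stimulus window of at least 5 s")
    if env is None:
        env = envelope(trace)
    fs = trace.fs
    i_on = int(round(onset * fs))
    i_pre = int(round(max(onset - pre_window, 0.0) * fs))
    i_end = min(int(round((offset + tail) * fs)), len(env) - 1)
    base_seg = env[i_pre:i_on]
    baseline = float(base_seg.mean())
    baseline_sd = float(base_seg.std(ddof=1))
    excess = np.clip(env[i_on:i_end + 1] - baseline, 0.0, None)
    area = float(np.trapezoid(excess, dx=1.0 / fs))
    if kin_smooth > 0:
        # decimate to ~100 Hz before the seconds-scale smoothing; the excess
        # is already band-limited to 25 Hz so block-means lose nothing
        ds = max(int(fs / 100.0), 1)
        n_blocks = len(excess) // ds
        coarse = excess[: n_blocks * ds].reshape(n_blocks, ds).mean(axis=1)
        kin = gaussian_filter1d(coarse, kin_smooth * fs / ds, mode="nearest")
        step = ds
    else:
        kin, step = excess, 1
    peak = float(kin.max())
    i_pk = int(np.argmax(kin))
    time_to_peak = i_pk * step / fs
    decay_fraction = float(kin[-1] / peak) if peak > 0 else 0.0
    q = ResponseQuant(
        stimulus=stimulus_label, baseline=baseline, area=area, peak=peak,
        time_to_peak=time_to_peak, decay_fraction=min(decay_fraction, 1.0),
        kinetics_class="none", baseline_sd=baseline_sd,
    )
    q.kinetics_class = classify_kinetics(q, **classify_kwargs)
    return q


def classify_kinetics(q: ResponseQuant, tau_fast: float = 10.0,
                      phi_fast: float = 0.3, phi_slow: float = 0.6) -> str:
    """Fast/transient vs slow/sustained response kinetics.

    ``none`` if the peak does not clear the noise floor (3x baseline SD);
    ``fast_transient`` if the peak arrives within ``tau_fast`` seconds AND the
    envelope has decayed to <= ``phi_fast`` of peak by the window end;
    ``slow_sustained`` otherwise (late peak, or sustained-above-``phi_slow``
    tail; the ambiguous mid band is classed slow — not transient).
    """
    if q.peak <= 3.0 * q.baseline_sd:
        return "none"
    if q.time_to_peak <= tau_fast and q.decay_fraction <= phi_fast:
        return "fast_transient"
    return "slow_sustained"


def estimate_threshold(series: DoseResponseSeries):
    """Blank-referenced detection threshold of a dose–response series.

    The threshold is the lowest tested dose whose mean response area exceeds
    ``mean(blanks) + 3 * SD(blanks)``; ``None`` if no dose qualifies.

    Returns
    -------
    (threshold, flags) : (float | None, np.ndarray of bool)
        Threshold in mol/m^3 and the per-dose detection flags.
    """
    if np.any(np.diff(series.doses) <= 0):
        raise ValueError("doses must be strictly ascending")
    blanks = series.blanks
    sd = float(blanks.std(ddof=1)) if blanks.size > 1 else 0.0
    criterion = float(blanks.mean()) + 3.0 * sd
    means = np.array([float(np.mean(r)) for r in series.responses])
    flags = means > criterion
    hits = np.nonzero(flags)[0]
    threshold = float(series.doses[hits[0]]) if hits.size else None
    return threshold, flags


def response_heatmap(areas: pd.DataFrame) -> pd.Series:
    """Per-leg-normalised mean relative response per compound.

    ``areas`` is a DataFrame indexed by leg (rows) with one column per
    compound, holding response areas.  Each leg is scaled to its own maximal
    area before averaging across legs, so absolute recording gain cancels;
    legs with no response anywhere are excluded with a warning.  Values lie
    in [0, 1].
    """
    if areas.shape[0] < 1:
        raise ValueError("need at least one leg")
    row_max = areas.max(axis=1)
    dead = row_max <= 0
    if dead.any():
        warnings.warn(f"excluding all-zero legs: {list(areas.index[dead])}", stacklevel=2)
        areas = areas.loc[~dead]
        row_max = row_max.loc[~dead]
    if areas.shape[0] == 0:
        raise ValueError("all legs were zero")
    normalised = areas.div(row_max, axis=0)
    return normalised.mean(axis=0)
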