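"""Trace-level kinetic observables.

Turns intensity traces into the quantities the assay is built around: the
reaction time zero (completion of the reagent-exchange baseline rise),
binding / dissociation step events, per-molecule first-arrival times,
antibody dwell times with monosome/polysome and censoring flags, field-level
binding-count time courses, the specific-to-nonspecific binding ratio
(SNBR), and Kaplan-Meier survival curves of bound antibodies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._changepoint import pelt_mean
from .simulate import Trace

__all__ = [
    "StepEvent",
    "EventSeries",
    "CountTimecourse",
    "SurvivalCurve",
    "Dwell",
    "detect_time_zero",
    "detect_steps",
    "first_arrival",
    "dwell_times",
    "binding_count_timecourse",
    "nonspecific_count_timecourse",
    "compute_snbr",
    "survival_curve",
    "analyze_trace",
]


@dataclass(frozen=True)
class StepEvent:
    time: float
    direction: str       # "up" | "down"
    amplitude: float     # absolute level change, > 0


@dataclass
class Dwell:
    duration: float
    censored: bool
    monosome: bool
    start: float = 0.0
    amplitude: float = 0.0


@dataclass
class EventSeries:
    """Detected events of one trace, with derived first-arrival and dwells."""

    trace_id: int
    t0: float
    events: list[StepEvent] = field(default_factory=list)
    first_arrival_s: float | None = None
    first_arrival_censored: bool = False
    censor_time: float | None = None
    dwells: list[Dwell] = field(default_factory=list)
    valid: bool = True
    invalid_reason: str | None = None


@dataclass
class CountTimecourse:
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


@dataclass
class SurvivalCurve:
    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


# ---------------------------------------------------------------------------
# time zero


def detect_time_zero(trace: Trace, rise_sigma: float = 5.0,
                     plateau_window_s: float = 30.0,
                     noise_sd: float | None = None) -> float:
    """Reaction time zero: when the baseline reaches 90% of its plateau.

    The pre-delivery level is the median of the earliest frames; the plateau
    is the median of a window starting at the rise.  Raises if the trace
    shows no rise (starts at plateau, or never leaves the pre level).
    """
    y = trace.intensities
    if noise_sd is None:
        noise_sd = float(np.median(np.abs(np.diff(y)))) / (np.sqrt(2) * 0.6745)
        noise_sd = max(noise_sd, 1e-9)
    n_pre = max(3, int(round(2.0 / trace.frame_interval)))
    pre = float(np.median(y[:n_pre]))
    above = np.nonzero(y > pre + rise_sigma * noise_sd)[0]
    if len(above) == 0:
        raise ValueError("no reagent delivery found: trace never rises")
    rise_idx = int(above[0])
    if rise_idx < n_pre:
        raise ValueError("no reagent delivery found: trace starts at plateau")
    n_post = max(3, int(round(plateau_window_s / trace.frame_interval)))
    plateau = float(np.median(y[rise_idx:rise_idx + n_post]))
    target = pre + 0.9 * (plateau - pre)
    reached = np.nonzero(y >= target)[0]
    reached = reached[reached >= rise_idx - 1]
    if len(reached) == 0:
        raise ValueError("no reagent delivery found: rise never completes")
    return float(trace.times[int(reached[0])])


def field_time_zero(traces: list[Trace], **kwargs) -> float:
    """Shared t0 for one field of view: the median of the per-trace values.

    Reagent exchange happens simultaneously for every molecule in the field,
    so a single field-level t0 is more robust than per-trace values.
    """
    vals = []
    for tr in traces:
        try:
            vals.append(detect_time_zero(tr, **kwargs))
        except ValueError:
            continue
    if not vals:
        raise ValueError("no reagent delivery found in any trace")
    return float(np.median(vals))


# ---------------------------------------------------------------------------
# step detection


def _merge_small_steps(y: np.ndarray, breaks: list[int], min_amp: float) -> list[int]:
    """Drop change points whose level difference is below threshold."""
    breaks = list(breaks)
    while True:
        edges = [0] + breaks + [len(y)]
        means = [y[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
        diffs = [abs(means[i + 1] - means[i]) for i in range(len(means) - 1)]
        if not diffs:
            return breaks
        worst = int(np.argmin(diffs))
        if diffs[worst] >= min_amp:
            return breaks
        del breaks[worst]


def detect_steps(trace: Trace, min_amplitude_sigma: float = 5.0,
                 t0: float | None = None, noise_sd: float | None = None,
                 penalty_factor: float = 3.0) -> list[StepEvent]:
    """Binding/dissociation steps by penalized change-point segmentation.

    The post-t0 portion of the trace is segmented into piecewise-constant
    levels (L2 cost, penalty ``penalty_factor * sigma^2 * log(n)``); level
    changes with ``|delta| >= min_amplitude_sigma * sigma`` become events.
    Event time is the first frame of the new level; amplitude is the level
    difference.
    """
    y = trace.intensities
    t = trace.times
    if t0 is not None:
        keep = t >= t0
        y, t = y[keep], t[keep]
    n = len(y)
    if n < 3:
        return []
    if noise_sd is None:
        noise_sd = float(np.median(np.abs(np.diff(y)))) / (np.sqrt(2) * 0.6745)
        noise_sd = max(noise_sd, 1e-9)
    penalty = penalty_factor * noise_sd**2 * np.log(n)
    breaks = pelt_mean(y, penalty)
    breaks = _merge_small_steps(y, breaks, min_amplitude_sigma * noise_sd)
    events = []
    edges = [0] + breaks + [n]
    means = [y[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
    for i, b in enumerate(breaks):
        delta = means[i + 1] - means[i]
        events.append(StepEvent(
            time=float(t[b]),
            direction="up" if delta > 0 else "down",
            amplitude=abs(float(delta)),
        ))
    return events


# ---------------------------------------------------------------------------
# first arrival and dwells


def first_arrival(events: list[StepEvent], t0: float,
                  movie_end: float) -> tuple[float | None, bool]:
    """First-arrival time t1 = (first up event) - t0, or censored.

    Returns ``(t1, censored)``; censored means no up event by ``movie_end``
    and then t1 is the censoring time ``movie_end - t0``.  An up event before
    t0 marks the trace as a pre-delivery artifact (raises ValueError); the
    caller should exclude the trace.
    """
    ups = [e for e in events if e.direction == "up"]
    if ups and ups[0].time < t0:
        raise ValueError("up event before reagent delivery: pre-delivery artifact")
    if not ups:
        return movie_end - t0, True
    return ups[0].time - t0, False


def dwell_times(events: list[StepEvent], movie_end: float,
                amplitude_rtol: float = 0.5) -> list[Dwell]:
    """Pair binding (up) steps with the matching dissociation (down) steps.

    Each up is paired with the next unconsumed down whose amplitude matches
    within ``amplitude_rtol`` relative tolerance.  Ups never matched by the
    end of the movie are censored at ``movie_end``.  A dwell is a monosome
    event when no other antibody is bound at any point during it.  Downs
    with no prior up are logged as orphans and ignored.
    """
    ups = [(e.time, e.amplitude) for e in events if e.direction == "up"]
    downs = [(e.time, e.amplitude) for e in events if e.direction == "down"]
    used = [False] * len(downs)
    dwells: list[Dwell] = []
    for t_up, amp in ups:
        match = None
        for j, (t_dn, amp_dn) in enumerate(downs):
            if used[j] or t_dn <= t_up:
                continue
            if abs(amp_dn - amp) <= amplitude_rtol * max(amp, amp_dn):
                match = j
                break
        if match is None:
            dwells.append(Dwell(duration=movie_end - t_up, censored=True,
                                monosome=True, start=t_up, amplitude=amp))
        else:
            used[match] = True
            dwells.append(Dwell(duration=downs[match][0] - t_up, censored=False,
                                monosome=True, start=t_up, amplitude=amp))
    n_orphans = used.count(False)
    if n_orphans:
        warnings.warn(f"{n_orphans} dissociation step(s) without a prior binding; ignored")

    # monosome flag: no concurrent occupancy with any other dwell
    for i, d in enumerate(dwells):
        for j, o in enumerate(dwells):
            if i == j:
                continue
            if d.start < o.start + o.duration and o.start < d.start + d.duration:
                d.monosome = False
    return dwells


def select_dwells(dwells: list[Dwell], monosome_only: bool = True,
                  include_censored: bool = False) -> list[float]:
    """Dwell durations for fitting (monosome-only, uncensored by default)."""
    return [d.duration for d in dwells
            if (include_censored or not d.censored)
            and (not monosome_only or d.monosome)]


def analyze_trace(trace: Trace, t0: float | None = None,
                  min_amplitude_sigma: float = 5.0) -> EventSeries:
    """Full per-trace reduction: t0, steps, first arrival, dwells."""
    if t0 is None:
        t0 = detect_time_zero(trace)
    movie_end = float(trace.times[-1])
    events = detect_steps(trace, min_amplitude_sigma=min_amplitude_sigma, t0=t0)
    series = EventSeries(trace_id=trace.trace_id, t0=t0, events=events)
    try:
        t1, cens = first_arrival(events, t0, movie_end)
    except ValueError as exc:
        series.valid = False
        series.invalid_reason = str(exc)
        return series
    series.first_arrival_s = t1
    series.first_arrival_censored = cens
    if cens:
        series.censor_time = t1
    series.dwells = dwell_times(events, movie_end)
    return series


# ---------------------------------------------------------------------------
# field-level observables


def binding_count_timecourse(series_list: list[EventSeries],
                             times: np.ndarray) -> CountTimecourse:
    """Concurrently bound antibodies per frame, summed over the field."""
    times = np.asarray(times, dtype=float)
    counts = np.zeros(len(times), dtype=int)
    for s in series_list:
        if not s.valid:
            continue
        for e in s.events:
            if e.direction == "up":
                counts += times >= e.time
            else:
                counts -= times >= e.time
    counts = np.clip(counts, 0, None)
    return CountTimecourse(times=times, counts=counts)


def nonspecific_count_timecourse(arrival_times: np.ndarray,
                                 times: np.ndarray) -> CountTimecourse:
    """Cumulative nonspecific arrivals (never released) per frame."""
    arr = np.sort(np.asarray(arrival_times, dtype=float))
    times = np.asarray(times, dtype=float)
    return CountTimecourse(times=times,
                           counts=np.searchsorted(arr, times, side="right"))


def compute_snbr(specific: CountTimecourse, nonspecific: CountTimecourse,
                 mrna_density_ratio: float = 1.0,
                 plateau_fraction: float = 0.1) -> float:
    """Specific-to-nonspecific binding ratio at the specific-binding plateau.

    The plateau is the mean of the final ``plateau_fraction`` of the specific
    curve; the nonspecific level over the same time window is rescaled by
    ``mrna_density_ratio`` to correct for unequal immobilized mRNA in the
    nonspecific channel.  Returns +inf when the nonspecific plateau is zero.
    """
    t_start = specific.times[-1] - plateau_fraction * (
        specific.times[-1] - specific.times[0])
    spec = float(specific.counts[specific.times >= t_start].mean())
    nons = float(nonspecific.counts[nonspecific.times >= t_start].mean())
    nons /= mrna_density_ratio
    if nons == 0:
        warnings.warn("zero nonspecific plateau; SNBR reported as +inf")
        return float("inf")
    return spec / nons


def survival_curve(durations: np.ndarray, observed: np.ndarray) -> SurvivalCurve:
    """Kaplan-Meier survival of bound antibodies with right-censoring.

    ``durations``: time from cohort start to loss (or to censoring);
    ``observed``: True where the loss was seen, False for censored spots.
    """
    durations = np.asarray(durations, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if len(durations) == 0:
        raise ValueError("empty cohort")
    from lifelines import KaplanMeierFitter
    km = KaplanMeierFitter()
    km.fit(durations, event_observed=observed)
    times = km.survival_function_.index.to_numpy(dtype=float)
    surv = km.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array([int((durations >= t).sum()) for t in times])
    return SurvivalCurve(times=times, survival=surv, n_at_risk=at_risk)


# ---------------------------------------------------------------------------
# tabular output


def events_to_frame(series_list: list[EventSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for e in s.events:
            rows.append({"trace_id": s.trace_id, "time_s": e.time,
                         "direction": e.direction, "amplitude": e.amplitude})
    return pd.DataFrame(rows, columns=["trace_id", "time_s", "direction", "amplitude"])


def arrivals_to_frame(series_list: list[EventSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        if not s.valid or s.first_arrival_s is None:
            continue
        rows.append({"trace_id": s.trace_id, "t1_s": s.first_arrival_s,
                     "censored": s.first_arrival_censored})
    return pd.DataFrame(rows, columns=["trace_id", "t1_s", "censored"])


def dwells_to_frame(series_list: list[EventSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for d in s.dwells:
            rows.append({"trace_id": s.trace_id, "dwell_s": d.duration,
                         "censored": d.censored, "monosome": d.monosome})
    return pd.DataFrame(rows, columns=["trace_id", "dwell_s", "censored", "monosome"])
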