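"""End-to-end orchestration: simulate -> (render/process movie) -> events -> fits.

`run_pipeline` executes the requested stages from a `RunConfig` and writes
every intermediate artifact (traces CSV, ground-truth JSON, TIFF stacks,
event/arrival/dwell tables, fit JSON) plus a summary report into the output
directory.  Identical seeds give identical outputs.

`generate_fixtures` produces the small self-contained datasets that emulate
the assay's experiment archetypes: a specific channel, a nonspecific-only
channel, a pre-exposed-epitope recognition measurement, a stalled-translation
photostability cohort, a hairpin comparison pair, and a small rendered movie.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import events as ev
from . import kinetics as kin
from .movie import render_movie, write_movie
from .simulate import (FieldSimulation, SimParams, simulate_field,
                       write_traces_csv, write_truth_json)

__all__ = ["RunConfig", "run_pipeline", "generate_fixtures", "PRESETS"]

PRESETS = ("ye_specific", "ye_nonspecific", "prebound_recognition",
           "stalled_survival", "hairpin_pair", "movie_small")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (JSON round-trip stable)."""

    sim: SimParams = field(default_factory=SimParams)
    n_mrna: int = 100
    render: bool = False                 # trace-level by default
    movie_shape: tuple[int, int] = (64, 64)
    psf_sigma: float = 1.5
    background: float = 10.0
    min_amplitude_sigma: float = 5.0
    n_boot: int = kin.DEFAULT_N_BOOT
    mrna_density_ratio: float = 1.0
    out_dir: str = "ribotrace_run"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["movie_shape"] = list(self.movie_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimParams.from_dict(d["sim"])
        if "movie_shape" in d:
            d["movie_shape"] = tuple(d["movie_shape"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return (and write) the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim.replace(seed=config.seed)
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=1)

    field_sim = simulate_field(sim, config.n_mrna)
    traces = field_sim.traces
    write_traces_csv(traces, out / "traces.csv")
    write_truth_json([tr.truth for tr in traces if tr.truth is not None],
                     out / "truth.json")

    if config.render and traces:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                           spawn_key=(7,)))
        h, w = config.movie_shape
        margin = 3 * config.psf_sigma + 1
        pos = np.column_stack([
            rng.uniform(margin, w - 1 - margin, size=len(traces)),
            rng.uniform(margin, h - 1 - margin, size=len(traces)),
        ])
        movie = render_movie(traces, pos, config.psf_sigma,
                             config.background, sim, shape=config.movie_shape)
        write_movie(movie, out / "movie.tif", out / "movie.json")

    # event detection on the trace level
    t0 = ev.field_time_zero(traces) if traces else math.nan
    series = [ev.analyze_trace(tr, t0=t0,
                               min_amplitude_sigma=config.min_amplitude_sigma)
              for tr in traces]
    ev.events_to_frame(series).to_csv(out / "events.csv", index=False)
    arrivals = ev.arrivals_to_frame(series)
    arrivals.to_csv(out / "arrivals.csv", index=False)
    dwells_df = ev.dwells_to_frame(series)
    dwells_df.to_csv(out / "dwells.csv", index=False)

    report: dict = {
        "seed": config.seed,
        "n_mrna": config.n_mrna,
        "t0_s": t0,
        "n_invalid_traces": sum(not s.valid for s in series),
        "n_arrivals": int((~arrivals["censored"]).sum()) if len(arrivals) else 0,
        "censoring_fraction": (float(arrivals["censored"].mean())
                               if len(arrivals) else math.nan),
    }

    t1 = arrivals.loc[~arrivals["censored"], "t1_s"].to_numpy()
    if len(t1) >= 100:
        fit = kin.ShiftedLogNormalModel(t1).fit(n_boot=config.n_boot,
                                                seed=config.seed)
        report["first_arrival_fit"] = {
            "x0_s": fit.x0, "mu": fit.mu, "sigma": fit.sigma,
            "y0": fit.y0, "mean_s": fit.mean, "peak_s": fit.peak,
            "se_mean_s": fit.se_mean, "se_peak_s": fit.se_peak, "n": fit.n,
        }

    mono = dwells_df.query("monosome and not censored")["dwell_s"].to_numpy()
    if len(mono) >= 50:
        dfit = kin.LogNormalDwellModel(mono).fit(n_boot=config.n_boot,
                                                 seed=config.seed)
        rate = kin.elongation_rate(dfit.mean, sim.n_codons)
        report["dwell_fit"] = {
            "mu": dfit.mu, "sigma": dfit.sigma,
            "mean_s": dfit.mean, "se_mean_s": dfit.se_mean, "n": dfit.n,
            "elongation_rate_aa_s": rate,
        }
        if len(t1) >= 100:
            prof = kin.asynchrony_profile(t1, dfit.mean)
            report["asynchrony"] = {
                "interval_width_s": prof.interval_width_s,
                "fractions": prof.fractions.tolist(),
                "remainder": prof.remainder,
            }

    # SNBR from the specific channel vs the field's nonspecific log
    if traces:
        times = traces[0].times
        spec = ev.binding_count_timecourse(series, times)
        nons = ev.nonspecific_count_timecourse(field_sim.nonspecific_times, times)
        if nons.counts[-1] > 0:
            report["snbr"] = ev.compute_snbr(spec, nons,
                                             config.mrna_density_ratio)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report


# ---------------------------------------------------------------------------
# fixtures


def generate_fixtures(preset: str, seed: int = 0, out_dir: str | Path | None = None):
    """Generate one of the assay's archetypal datasets.

    Returns the in-memory dataset; when ``out_dir`` is given the artifacts
    are also written there.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    base = SimParams(seed=seed)

    if preset == "ye_specific":
        data = simulate_field(base, 100)
    elif preset == "ye_nonspecific":
        # 2.3-fold denser immobilized mRNA but no epitope: nonspecific only
        p = base.replace(nonspecific_rate=base.nonspecific_rate * 2.3)
        data = simulate_field(p, 0)
    elif preset == "prebound_recognition":
        # epitopes already exposed: t1 is the pure antibody-recognition delay
        data = kin.draw_double_exponential(
            4516, base.tau_fast, base.tau_slow, base.fast_fraction, rng)
    elif preset == "stalled_survival":
        # elongation disabled: only the translation-irrelevant loss clock runs
        n, horizon = 1998, 30.0 * 60.0
        loss = rng.exponential(1.0 / base.bleach_rate, size=n)
        observed = loss <= horizon
        data = (np.minimum(loss, horizon), observed)
    elif preset == "hairpin_pair":
        # identical conditions except a shift of the initiation distribution
        delta = 78.0   # s
        minus_hp = base
        plus_hp = base.replace(first_init_x0=base.first_init_x0 + delta,
                               seed=seed + 1)
        data = (simulate_field(minus_hp, 120), simulate_field(plus_hp, 120),
                delta)
    elif preset == "movie_small":
        p = base.replace(movie_length=580.0, frame_interval=2.0)
        fld = simulate_field(p, 6)
        margin = 3 * 1.5 + 1
        pos = np.column_stack([
            rng.uniform(margin, 48 - 1 - margin, size=6),
            rng.uniform(margin, 48 - 1 - margin, size=6),
        ])
        data = render_movie(fld.traces, pos, psf_sigma=1.5, background=10.0,
                            params=p, shape=(48, 48))
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if isinstance(data, FieldSimulation):
            write_traces_csv(data.traces, out / f"{preset}_traces.csv")
            np.savetxt(out / f"{preset}_nonspecific.csv",
                       data.nonspecific_times, header="arrival_s")
        elif preset == "prebound_recognition":
            np.savetxt(out / f"{preset}_t1.csv", data, header="t1_s")
        elif preset == "stalled_survival":
            np.savetxt(out / f"{preset}_loss.csv",
                       np.column_stack([data[0], data[1]]),
                       header="duration_s observed")
        elif preset == "hairpin_pair":
            write_traces_csv(data[0].traces, out / "minus_hp_traces.csv")
            write_traces_csv(data[1].traces, out / "plus_hp_traces.csv")
        elif preset == "movie_small":
            write_movie(data, out / "movie_small.tif", out / "movie_small.json")
    return data
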