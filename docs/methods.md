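# Methods

## Generative model

Each surface-tethered mRNA is simulated independently on a "kinetics clock"
whose zero is the completion of reagent exchange.

**First-round initiation.** Drawn from a shifted log-normal,
t = x₀ + LogNormal(μ, σ). The assay only characterises the *distribution* of
first-round initiation times, not the underlying multi-step mechanism, so
the simulator samples from the fitted functional form rather than from a
mechanistic scanning model. Defaults (x₀ = 60 s, μ = ln 240, σ = 0.9) give a
histogram peaking near 3 min with a heavy tail beyond 20 min, i.e. first
arrivals spanning roughly 2–30+ min — the asymmetric, highly asynchronous
regime the assay is designed to resolve.

**Epitope exposure.** The tag becomes antibody-accessible after the ribosome
has translated `tag_exposure_aa` residues: the 22-aa 3xFLAG tag plus the
nascent chain protected by the exit tunnel. The protected length is 30–40 aa
depending on nascent-chain conformation; 35 aa is the default point
estimate, and `mean_initiation_time` propagates the full 30–40 band (at
~2.45 aa/s the 10-aa band is ~4.1 s, negligible against minutes-scale
initiation). Default `tag_exposure_aa = 57`.

**Antibody recognition.** A two-component exponential mixture: a fast
component (τ₁ = 3.9 s, weight 13/14) for fully exposed epitopes and a slow
component (τ₂ = 38 s) lumping the cases where the chain must elongate
further before the tag clears the tunnel. Recognition delays that would land
after termination are discarded as unobserved rounds.

**Unbinding.** The antibody leaves with the peptide at termination
(initiation + n_codons/rate). An independent exponential clock lumps
translation-irrelevant losses — antibody dissociation from the intact chain
and photobleaching — because the assay measures only their sum. Its default
rate, −ln(0.9)/(30 min), reproduces the calibrated ~10% spot loss over a
30-minute stalled-translation incubation.

**Re-initiation (polysomes).** Inter-initiation waits are exponential with
mean `reinit_mean` (default 120 s), subject to a clearance rule: a new
initiation cannot occur before the previous ribosome has translated
`clearance_codons` (default 35). How long the first recruited small subunit
sequesters the 5′ end is not characterised experimentally; simple clearance
is the minimal testable rule, and `reinit_mean = inf` gives monosome-only
data. Both are config, not conclusions.

**Traces and movies.** A trace is baseline ramp + per-antibody steps +
Gaussian noise. The baseline rises linearly over the 3.5-s reagent-exchange
dead time (within the observed 3–4 s) to the diffusing-antibody plateau;
time zero for kinetics is the completion of this rise. Step amplitudes are
(dye count × unit brightness) with dye counts uniform on 2–7, matching the
antibody labelling ratio; dye photophysics (blinking) is not modelled, as
the trajectories this emulates show none. Movies render each bound antibody
as a symmetric 2D Gaussian (peak amplitude = step amplitude) at a continuous
position, plus constant background, optional rigid drift, and Gaussian or
Poisson pixel noise. Frames are 0-indexed with pixel centres at integers;
frame k is at time k × frame_interval (default 2 s, within the 0.5–2 s
acquisition range).

**Nonspecific binding.** A homogeneous Poisson process per field
(default 0.002 arrivals/s) whose arrivals never release, giving the linear
accumulation characteristic of surface-stuck antibodies. The default rate is
set so that a typical simulated field reproduces the ≥20-fold
specific-to-nonspecific binding ratio (SNBR) characteristic of the yeast-
extract assay; the SNBR plateau window is the final 10% of acquisition
(the window is otherwise unspecified).

## Imaging reduction

Standard single-molecule TIRF processing, each stage testable against the
simulator's ground truth: rigid drift by upsampled phase cross-correlation
against frame 0 (sub-pixel via Fourier upsampling); background by a
per-frame median filter of radius 10 × psf_sigma; spot candidates by
thresholded local maxima (robust MAD noise scale) with non-maximum
suppression within 2 × psf_sigma; localization by least-squares fit of a
symmetric 2D Gaussian plus offset in a window of half-width 3 × psf_sigma
(fit fails when the window clips the frame edge, the centre leaves the
window, or σ falls outside [0.5, 3] × psf_sigma). Trace photometry sums a
fixed circular aperture (radius 2 × psf_sigma) at the mRNA map positions —
not per-frame re-detection, because first-arrival analysis needs intensity
before any antibody binds — normalised by the PSF volume and the aperture's
enclosed-energy fraction so trace units equal PSF peak amplitude. Molecules
within 3 × psf_sigma of the border are excluded.

## Event detection

Steps are called by penalized least-squares change-point segmentation
(PELT, L2 cost, penalty 3·σ²·log n with σ from the MAD of first
differences), then level changes below `min_amplitude_sigma` × σ (default 5)
are merged away. Change-point segmentation was chosen over threshold
crossing because step amplitudes are heterogeneous (2–7 dyes per antibody).
Up events before t₀ invalidate the whole trace (surface junk), not just the
event. Dwells pair each up with the next amplitude-compatible down (50%
relative tolerance); unpaired ups are right-censored at movie end; a dwell
is a monosome event when no other antibody is bound during it, and dwell
fitting uses uncensored monosome events only. Censored first arrivals are
excluded from histogram fitting (the shifted log-normal is fitted to
observed-arrival histograms) but counted and reported as a censoring
fraction.

## Fitting

* **Double exponential** — maximum likelihood on raw delays (primary), with
  a binned least-squares mode mirroring histogram fitting; the two agree
  within combined errors on large samples. Parameterised as
  (log τ₁, log τ₂, logit p) with multi-start Nelder–Mead; τ₁ ≤ τ₂ by
  convention. A fit is flagged degenerate when the components collapse
  (τ₂/τ₁ < 1.5), an amplitude vanishes, or the likelihood-ratio statistic
  against a single exponential is below 6.
* **Shifted log-normal** — least squares of
  y₀ + A·pdf(x; x₀, μ, σ) on Freedman–Diaconis binned counts (the additive
  y₀ floor makes this a histogram-height model, so a histogram fit is the
  faithful estimator; bin rule overridable). x₀ is constrained to
  [0, min sample]; three x₀ starts guard against local minima. Derived
  mean x₀ + e^(μ+σ²/2) and peak x₀ + e^(μ−σ²); the fitted mean matches the
  numerical first moment of the fitted density to <0.1%.
* **Log-normal dwell** — closed-form MLE on log dwell times.
* **Errors** — nonparametric bootstrap over trajectories (200 replicates,
  seeded), standard deviation of the replicate estimates; peak/mean errors
  by bootstrap propagation. Condition comparisons (e.g. ±hairpin) report
  peak and mean shifts with independent-bootstrap combined errors.

The elongation rate is n_codons / mean dwell. This follows the field's
convention of treating the dwell as the total decoding time; strictly the
antibody binds only after the tag-exposure segment (~57 aa) is translated,
so the convention overestimates the rate by a few percent at default
parameters — an approximation inherited deliberately, not an estimator bug.
The asynchrony profile divides the first-arrival distribution, starting at
its earliest arrival, into 14 consecutive windows one mean-elongation-time
wide and reports the fraction per window plus the later-arrival remainder.

## What the simulator does and does not emulate

It reproduces the statistical structure the analysis relies on: shifted
log-normal first arrivals, mixture-exponential recognition, log-normal-like
dwell variation arising only through recognition delays (dwells are
otherwise deterministic per round at fixed rate), linear nonspecific
accumulation, exponential translation-irrelevant loss, multi-dye amplitude
heterogeneity, and the baseline-rise time origin. It does not emulate
codon-to-codon elongation stochasticity, fluorophore blinking, EMCCD gain
noise, flow-induced focus drift, or mechanistic initiation. Passing tests
therefore validate the estimators and pipeline on data with the assumed
structure; they do not certify performance on real recordings whose noise
departs from it.

## Numerical choices and problem sizes

Stochastic tests fix seeds and use 3-standard-error (or closed-form
binomial/Poisson/KS) bands. Test problem sizes are chosen as the smallest
that make the checks sharp: 10⁵ draws for moment oracles, 2000 molecules for
survival calibration, ~40–150 traces for detector recovery rates, 64×64 ×
≤600-frame movies for the imaging pipeline, and published sample sizes
(n = 4516 recognition delays, n = 515 dwells) for the acceptance-level
parameter-recovery runs. Degenerate inputs are defined errors: tags longer
than the ORF, traces with no baseline rise, empty survival cohorts,
nonpositive dwells, and frame-shifting insert lengths all raise.

## Known limitations

Censoring-aware (survival) likelihoods for first arrivals are deliberately
out of scope — censored arrivals are excluded as in histogram fitting. The
occupancy rule for re-initiation is an assumption; dwell statistics under
heavy polysome loading depend on it. The SNBR depends on field density
(mRNAs per field), which is a free experimental parameter; the packaged
default represents a typical high-quality field.
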