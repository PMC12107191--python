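# Methods

This note documents the models behind `synapse-capture`, the defaults that
matter, the design choices that were genuinely open, and the limits of what
the synthetic data can show.

## Membrane physics

Tethered-antigen mobility on a supported bilayer is predicted with a
Stokes–Einstein-like closed form,

    D = k_B · T · λ / (4π · η_m · R),      η_m = η_mb · h,

where η_m is the surface viscosity (bulk viscosity η_mb times bilayer
thickness h, units Pa·s·m), λ the membrane-perturbation length and R the
radius of the diffusing inclusion. Defaults: λ = 0.5 nm (one lipid),
R = 1 nm (two lipids — a doubly biotinylated DNA tether through one
streptavidin), T = 298 K, h = 5.9 nm (DOPC) and 6.3 nm (DPPC), with
surface viscosities 8.4×10⁻¹¹ (DOPC, fluid) and 3.0×10⁻⁹ Pa·s·m (DPPC,
gel). The temperature entering the formula is not uniquely dictated by the
assay (cells are imaged at 37 °C but bilayer viscosities are tabulated
near room temperature); 298 K reproduces both measured diffusion constants
within 5 %, 310 K within 7 %, and the parameter is exposed. The full
Saffman–Delbrück treatment with its logarithmic size dependence is
deliberately out of scope: the λ-form is the model used, not an
approximation of something else in the package.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (parameters, seed) and returns a
`GroundTruth` record. Defaults mirror the acquisition settings of the
assay the pipeline targets: 8 s/frame for extraction movies, 10 ms/frame
for single-particle tracking, Poisson photon noise on a uniform
background, Gaussian PSF.

- **Trajectories.** Brownian steps have per-axis variance 2·D·dt;
  subdiffusion uses fractional Gaussian noise with Hurst H = α/2 sampled
  exactly via the Cholesky factor of the fGN covariance, so the ensemble
  MSD is 4·scale·τ^α by construction. Localization error is additive
  Gaussian noise on the reported (not true) positions, default 0.
- **FRAP.** Single-exponential recovery in half-time form with a mobile
  fraction; pre-bleach level 1, post-bleach floor F₀ (default 0).
- **Extraction experiments.** The cell footprint is a disk whose radius
  follows a saturating spreading curve (3 → 7 µm, time constant 120 s).
  Rupture times are a memoryless exponential renewal process — the assay
  reports only mean times to first extraction (74 s on the gel-phase,
  421 s on the fluid bilayer), so the exponential is the minimal
  assumption, and the mean is a parameter, not a fit. Event positions are
  uniform in area over the current footprint (or over a chosen zone).
  Mechanical force is *not* modelled: the ~10 pN rupture threshold is a
  property of the DNA sensor, not of this computation.
- **Calcium.** Four trace archetypes (oscillatory, maintained, unique,
  nonresponsive) built from a gamma-like transient with amplitude
  ΔF/F = 2 over baseline 100 and Gaussian noise (default sd 2 counts,
  i.e. 2 % of baseline — typical of the indicator traces this emulates).
- **Translocation.** A nucleus disk inside a cytoplasm annulus with an
  exactly controlled nuclear-to-cytoplasmic intensity ratio before noise.

What passing tests on these data do **not** show: robustness to uneven
illumination, bleaching during acquisition, spot motion after extraction,
overlapping cells, non-disk footprints, or indicator saturation. The
generator's `STUDY_PRESETS` table carries the measured per-bilayer values
(D, α, FRAP parameters, extraction kinetics, responder rates) purely as
realistic presets and documentation — they are measurements of real cells
and are never treated as quantities a simulation must reproduce.

## Tracking and MSD estimation

Detection: difference-of-Gaussians band-pass at the PSF width, local
maxima above median + k·(1.4826·MAD) of the image (default SNR k = 5),
subpixel centroid refinement in a ±2σ window, minimum separation 2σ
keeping the brighter spot. Linking: Hungarian assignment minimizing total
squared displacement under a hard per-frame gate (`max_disp`), gap closing
up to one missing frame; a greedy nearest-neighbour variant is available.
The optimal assignment is the default because it is the estimator the
correctness tests can pin against exhaustive min-cost matching.

MSD is time-averaged per track over all ordered pairs, ensemble-averaged
with pair-count weights. D comes from a weighted linear fit of the first
4 lags with a free intercept (the intercept absorbs the 4σ² localization
term; short-lag fitting limits correlation bias), reported per track and
summarized as the per-condition mean of track values — matching how
per-bilayer means are formed from trajectory ensembles. α is the OLS
slope of log MSD vs log τ over lags 1–10. Tracks shorter than 10 frames
are excluded from fitting. These ranges are package defaults, stated
rather than inferred; estimator validation shows |bias(D)| < 10 % and
|α̂ − α| < 0.05 at 500 tracks × 100 steps over D ∈ {0.057, 0.5, 1.9}
µm²/s and α ∈ {0.37, 0.75, 1.0}. The log–log estimator carries a small
(~0.03) downward finite-track bias at α = 1 and is not corrected for a
localization-noise floor, so estimator-recovery runs use noise-free
positions; with localization noise, α at short lags is biased low and a
noise-corrected estimator would be needed.

## FRAP fitting

Double normalization (bleach ROI / reference ROI, then / pre-bleach mean)
removes acquisition bleaching and gain. The default recovery model is the
single-exponential half-time form; fitted mobile fraction is
(F_p − F₀)/(1 − F₀). "Recovered to X %" is interpreted as the *plateau*
mobile fraction under pre-bleach-normalized units, not the value at the
last acquired frame. A plateau at or below the floor is reported as
mobile fraction 0 with a flag (the gel-phase regime), not as an error.

## Synapse zones and event detection

The footprint is segmented by Otsu threshold on the background-subtracted
membrane channel, largest component, hole filling and closing; the
centroid is intensity-weighted. The three concentric zones of equal
radial width are defined along the ray from the centroid through the
query point: normalized distance = |point − centroid| / (centroid-to-
boundary distance along that ray), with half-open thirds (exactly 1/3 →
peripheral, exactly 2/3 → distal). The ray convention handles non-
circular cells; an r_eq-normalized variant would differ there and the
normalized distance is reported so either can be derived. Zones are
recomputed every frame because the footprint grows as the cell spreads.
On a perfect disk the zones cover 1/9 : 3/9 : 5/9 of the area.

An unquenching event is a linked spot track whose first detection is
after frame 0, with no detection within 2σ of that location in the
preceding `min_persist_frames` frames (default 3, anti-blinking), and
persisting at least that many frames. Onset time is first-detection time
minus contact time; contact is defined operationally as the first frame
whose segmented area exceeds 10 µm². Event intensity is taken from the
first detection frame (cluster size at extraction). Events within the
last `min_persist_frames − 1` frames of a movie cannot satisfy the
persistence rule and are excluded from recall accounting.

Extraction efficiency is internalized / bound total intensity per cell
(NaN-flagged when the bound total is non-positive). The affinity-
discrimination ratio averages cells per experiment first, forms the
high/low ratio per experiment, and reports the cross-experiment mean ±
SEM. Note the efficiency is only gain-invariant when both channels share
the same gain; unequal channel gains rescale it.

## Calcium classification

ΔF/F is computed against the pre-contact baseline. A responder reaches
ΔF/F ≥ 0.5 for ≥ 2 consecutive frames (configurable). Pattern rules —
≥ 3 peaks (prominence ≥ half the maximum, minimum separation 10 s) →
oscillatory; otherwise a plateau ≥ 50 % of the maximum for ≥ 50 % of the
post-onset trace → maintained; else unique — are this package's
operationalization of the four archetypes; the thresholds are exposed as
parameters. Activation by translocation is strict: N/C ratio > 1.

## Statistics

Inference follows the SuperPlots convention: the unit of inference is the
per-experiment mean (typically 3–4 experiments per condition); cells are
never pooled across experiments for tests. Paired comparisons use the
two-tailed paired t test on experiment means; correlations use Pearson r
with the t-transform p (dof n − 2). Raw p values are reported without
multiple-testing correction, mirroring standard practice in this assay
literature. Cells without events are excluded from intensity means but
kept in event-fraction denominators.

## Problem sizes and numerical choices

Estimator-validation runs use 500 tracks × 100 steps (D and α grids),
100 FRAP replicates at noise sd 0.02, ten 50-frame extraction movies
(~300 events) for detection quality, 10,000 points for the zone-geometry
check and 200 traces for the calcium confusion matrix — sizes at which
the binomial/sampling tolerances quoted above are meaningful. Ray-
boundary distances are found by 1 px coarse marching plus quarter-pixel
refinement; fits clamp D and the noise offset at zero; the fGN covariance
gets a 10⁻¹² diagonal jitter before Cholesky; degenerate inputs (zero
variance of paired differences, constant correlation inputs, empty
cluster sets, plateau-free recoveries) are flagged in results rather than
raised, so cohort loops never abort on a single degenerate cell.

## Known limitations

Segmentation assumes one dominant cell per field. Linking is frame-local
(no motion model), appropriate for near-static extraction spots and
short-lag diffusion but not for fast directed transport. The FRAP model
ignores diffusion-profile corrections (no Soumpasis fit yet). The
classifier thresholds were chosen from noiseless archetypes, and real
traces with drifting baselines would need detrending first.
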