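# Methods

## The population model

A labelling experiment is modelled as a two-component mixture over `n`
cells. A fraction `F` (default 0.44, the labelled fraction after a
30-minute pulse in a cycling human line) is in S phase and carries specific
replication signal; the rest (G1 + G2/M) carries only non-specific
background. Both components are log-normal, parameterised by their
arithmetic mean and CV:

| parameter | default | meaning |
|---|---|---|
| `mu_signal_R` | 300 a.u. | mean nuclear signal, replicating cells |
| `mu_signal_nonR` | 50 a.u. | mean background, non-replicating cells |
| `cv_R` | 0.25 | spread of the specific signal (replication activity varies through S) |
| `cv_nonR` | 0.10 | spread of the per-nucleus background (a mean over hundreds of pixels, so narrow) |
| `frac_g1/s/g2m` | 0.45 / 0.44 / 0.11 | phase fractions of a typical cycling line; S equals `frac_replicating` by invariant |
| `dna_g1`, `dna_cv` | 100 a.u., 0.05 | 2N DNA content and its measurement spread; 4N is fixed at 2× |

The default component ratio ρ = 6 sits at the upper end of what a good
anti-BrdU antibody/protocol achieves and is well above the ratio-of-3–4
guideline for clear separation. Log-normal components were chosen because
fluorescence intensities are positive and right-skewed; S-phase DNA content
is uniform on (2N, 4N) — the simplest model producing the classic bivariate
arc, with no replication-timing structure.

Rendering draws each nucleus as a disk (radius uniform on 8–14 px) on a
1024×1024 16-bit canvas. DAPI per-pixel intensity is
`dapi_gain · dna_content / area`, so *integrated* nuclear DAPI is
proportional to DNA content regardless of nucleus size; the signal channel
is flat at `true_signal` inside the footprint. Poisson shot noise plus
Gaussian read noise (sd 4 a.u.) are applied. Disk centres are rejection-
sampled with a pairwise separation of at least `r_i + r_j + 2` px so the
ground-truth mask has exactly one component per cell; a 400-cell cap per
canvas keeps density realistic (~15% area). Flow events multiply signal and
DNA by independent log-normal noise (CV 0.05, a typical cytometer DNA CV)
and are emitted in randomised order, 10,000 events per experiment.

Not emulated: point-spread-function optics, z-stacks, photobleaching,
illumination gradients, doublets/aggregates, nuclear shape irregularity,
and replication-timing substructure of S phase. Passing tests therefore
demonstrate correctness of the *computational chain* under a faithful but
idealised acquisition model, not robustness to every real-microscope
artifact.

## The R/non-R statistic

Nuclei are ranked by signal (stable descending sort). With labelled
fraction `f`:

- `n_top = round((f − 0.1)·n)` — the most-labelled group R,
- `n_bottom = round((0.9 − f)·n)` — the least-labelled group non-R,

each clamped to ≥ 1, with rounding half away from zero (at the canonical
f = 0.44, n = 10,000 every sane rounding gives 3,400 and 4,600). The
statistic is `mean(R) / mean(non-R)`. The 0.1-wide buffers on both sides of
the `f` boundary exclude borderline nuclei, so with well-separated
components the R group is a pure sample of replicating cells and non-R of
non-replicating ones. Preconditions: `0.1 < f < 0.9` and
`n ≥ max(⌈1/(f−0.1)⌉, ⌈1/(0.9−f)⌉)` so both groups are nonempty. Ties at a
group boundary are broken by input order; because tied values are equal,
the group means are unaffected.

Note on group sizes: the `(0.9 − f)` formula gives 4,600 least-labelled
nuclei at f = 0.44 and n = 10,000, not the full non-replicating complement
(1 − f)·n = 5,600. This implementation follows the formula — the buffered
bottom group — consistently with the top group's definition.

**Selection bias.** Because the groups are defined by *rank*, their means
are trimmed means of the mixture components: the R group is the top
0.34/F quantile band of the R component, the non-R group the bottom
0.46/(1−F) band of the background. For log-normal components the expected
group means have the closed form `m·[Φ(z_b−σ)−Φ(z_a−σ)]/(q_b−q_a)`, and at
the defaults the statistic runs ≈ 13% above the true component-mean ratio
ρ. The property tests check the estimator against this closed form rather
than against ρ itself. Two consequences:

- the statistic is scale-invariant and exactly 1.0 on constant input, but
  its *null* value on a homogeneous population exceeds 1 (≈ 1.1–1.2 at
  background CV 0.10), because ranking selects the background tails;
- a fully dissociated (30-minute washed) population is therefore judged
  "signal-free" by comparing its statistic with that null level, while the
  *component-mean* ratio `mean(S cells)/mean(non-S cells)` — computable on
  ground truth — is exactly `1 + retained·(ρ − 1)` in expectation and goes
  to 1.0. The pipeline reports both.

**F estimation.** The labelled fraction is estimated by a two-class Otsu
threshold on `log(signal + 1)`. The threshold is computed *exactly* over
all n − 1 splits of the sorted sample (maximising between-class variance
with prefix sums) rather than over histogram bins; binned Otsu can park the
cut inside a cluster through bin quantisation, which matters when the
classes are separated by a wide empty gap. The estimate carries a
reliability flag, false when the class means are separated by less than
3-fold — below the separation guideline, F cannot be called cleanly.

## Wash-dissociation kinetics

Specifically bound antibody dissociates during post-incubation washes as a
first-order process, `retained(t) = exp(−k_off·t)`. A single exponential is
the minimal model consistent with the three calibration points (100% at a
5-second wash, ≈ 20% after 5 min, ≈ 0 after 30 min); the default
`k_off = ln(5)/5 ≈ 0.322 min⁻¹` reproduces the 5-minute 80% loss exactly
and leaves 6.4×10⁻⁵ after 30 min. The 5-second wash is treated as t = 0
(decay over 5 s is ~2.7%, below measurement resolution). `fit_k_off`
regresses −log(retained) on t through the origin (the maximum-likelihood
rate under multiplicative log-normal error) and returns the slope with its
standard error; retained values must be floored at a detection limit before
fitting, since a true zero has no log.

Formaldehyde post-fixation traps the complex: the specific signal is
multiplied once by a concentration-dependent efficiency and decays no
further. The efficiency curve linearly interpolates the measured anchors
(0.05% → 0.827, 0.1% → 0.967, 0.2% → 1.023, 0.5% → 0.953, 1% → 1.05,
2% → 1.00, normalised to the 2% condition), is anchored at (0, 0), and is
constant above 2%. Efficiencies slightly above 1.0 are measurement noise
around the plateau and are kept as measured (validity bound 1.2) rather
than clipped. In the wash model, only the specific component of S-phase
cells decays; the non-specific background is left unchanged — the data do
not separate the two, and treating background as stable is the conservative
choice (a decaying background would only push the washed statistic closer
to 1). The quick-secondary-antibody alternative is modelled as
stabilisation with factor 1.0.

## Cell-cycle gating

Gating operates on (signal, DNA) pairs from either path — flow events or
per-nucleus measurements (`signal_mean`, `dapi_integrated`). The S gate is
the exact-Otsu threshold on log signal (shared with F estimation), or
optionally `mean + k·sd` of the signal-negative class (`k_sigma` mode,
default k = 3). DNA content is normalised by the G1 peak, located as the
highest mode of a Gaussian-KDE density of the signal-negative events (where
2N dominates); among signal-negative events, G1 is scaled DNA < 1.5 (3N)
and G2/M otherwise — a simple rectangle gate, no curved gates or doublet
discrimination. An all-zero signal vector is treated as an unlabelled
sample (no S events, DNA-only gating); a constant nonzero signal is an
error recommending a longer labelling pulse. Gating is invariant to
rescaling all DNA values, since normalisation absorbs scale.

## Pipeline, determinism and problem sizes

One global seed drives every stage (population seed, imaging seed + 1,
flow seed + 2, all below 2³¹); identical config + seed reproduces every
output file bit for bit (the manifest records sha256 hashes, and every CSV
and TIFF embeds the config hash and seed in a provenance header). Stage
failures propagate with the stage name attached.

Default problem sizes mirror the study design: 10,000 nuclei per scored
population and per flow experiment, with 200–400 nuclei per rendered
1024×1024 canvas (image-path statistics are computed on the rendered
subset, population statistics on the full table — both paths are
first-class). Simulation-based checks use 3–5 replicate seeds with 3-SE
criteria.

## Known limitations

- The trimmed-rank statistic's selection bias (above) means it should be
  read as a separation index, not an unbiased estimate of the component
  ratio; the bias grows with component CV and is analytically predictable.
- F estimation assumes a genuinely bimodal signal distribution; it errors
  (rather than guessing) on degenerate input and flags low separation.
- Segmentation is tuned for rounded, non-overlapping cultured-cell nuclei;
  heavily touching or irregular nuclei rely on the watershed split, whose
  seeds (distance-transform maxima at least one minimum-nucleus-diameter
  apart, raster-order tie-break) can merge deeply overlapping objects.
- The kinetics module fits a single rate; heterogeneous epitope
  accessibility (biexponential decay) is not modelled, as the calibration
  data do not support more than one rate.
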