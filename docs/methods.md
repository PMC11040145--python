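# Methods

## The detection problem

An Infinium methylation BeadChip reports, for each targeted CpG, two
fluorescence intensities: M (methylated allele) and U (unmethylated
allele), from which the methylation fraction is estimated as
beta = M / (M + U). Every probe also reads a nonzero optical/chemical
background, so when little or no template was captured for a locus the
two channels read roughly equal background and beta collapses towards
0.5. The attainable betas at total intensity T with per-channel
background B are bounded by B/T and 1 − B/T — the *beta-value envelope* —
which pinches to 0.5 at T = 2B (`theoretical_envelope`).

Detection calling asks, per probe, whether the observed signal is
distinguishable from background. In high-input samples a conservative
null (such as pOOBAH's out-of-band ECDF) is fine, because almost no true
signal sits near background. In low-input samples (picograms of DNA,
single-digit cell numbers) a large fraction of true signal is weak, and a
conservative null destroys biology. The envelope-based caller implemented
here (ELBAR) aims to mask only readings fully dominated by background.

## The algorithm

1. **Record pooling.** Each probe contributes an in-band record with
   total M + U; each Infinium-I probe additionally contributes its
   out-of-band (OOB) read pair as a record (oob_M + oob_U), since an OOB
   pair is a paired allele reading like any other. A flag
   (`oob_in_binning`) can restrict binning to in-band records.
2. **Intensity binning.** Records are binned into `nbins` equal-width
   bins of log2(total + 1) between the observed minimum and maximum of
   the positive totals; zero totals fall into bin 1. Bins with fewer than
   `min_per_bin` records merge into their lower-intensity neighbour
   (bin 1 merges upward) so quantiles are estimated on adequately
   populated bins.
3. **Envelope.** Per bin, the 5% and 95% quantiles of the record betas
   (linear interpolation between order statistics, position =
   level × (n − 1)). Bins with fewer than two defined betas are dropped
   with a warning.
4. **Background bins.** Scanning up from the lowest-intensity bin, the
   first bin whose envelope deviates from bin 1 by more than `tau`
   (max of the two absolute quantile shifts) marks the onset of real
   signal. If no bin deviates the sample is an *array-wide failure*: the
   whole array is indistinguishable from background. The call is still
   returned, with p-values computed from the all-bin pool, because such
   samples are legitimate (if empty) data points.
5. **Background pool.** Every in-band record in a background bin whose
   beta lies within the reference bin's envelope band contributes its
   max(M, U); negative controls contribute their raw intensities.
   Two aspects deserve emphasis:
   - *Per-record maxima.* The detection statistic is max(M, U) — the
     strongest reading the probe produced — so the pool stores the same
     statistic per background record. Pooling M and U as separate values
     would make the null a single-draw distribution while the statistic
     is the max of two draws, inflating the false-detection rate to
     roughly twice the nominal level.
   - *Intermediate-beta window* (`pool_beta_window`, default on). Only
     background-bin readings with intermediate methylation (inside the
     lowest bin's envelope band) model the background. This keeps weak
     but genuine signal — polarized betas at low intensity — out of the
     null, which is what makes the caller strictly more sensitive than
     the OOB baseline at every input level. The cost is a mild
     liberality: trimming extreme-beta background readings also trims
     the upper tail of the max(M, U) null, and the measured
     false-detection rate on background-only probes runs at ≈ 0.065–0.07
     for a nominal 0.05 threshold. This trade — sensitivity over exact
     false-positive control — is deliberate; the p-values should be read
     as measures of background influence, not exact tail probabilities.
     Setting `pool_beta_window=False` restores calibration (measured
     ≈ 0.05) at the price of pool contamination by weak signal, which
     can make the caller marginally more conservative than the OOB
     baseline at intermediate inputs.
6. **P-values.** Add-one ECDF: p = (1 + #{pool ≥ s}) / (|pool| + 1),
   strictly in (0, 1]. `mode="maxbg"` instead implements the hard
   threshold reading (p = 1 unless s exceeds the pool maximum). Masking
   sets beta to missing where p ≥ threshold (0.05 convention; the
   boundary masks).

### Baselines

* `poobah_detect` — per-channel ECDF of all OOB intensities read in that
  channel. Infinium-I probes are scored on their in-band channel with
  max(M, U); Infinium-II probes are scored in both channels (M in green,
  U in red) and take the smaller p-value.
* `negctl_detect` — per-channel normal fit (mean, ddof-1 variance) to
  negative controls; a probe's M + U is scored against the sum of its two
  channel nulls (means and variances add), upper tail.

### Defaults

| parameter | default | meaning |
|---|---|---|
| nbins | 20 | intensity bins before merging |
| min_per_bin | 100 | minimum records per retained bin |
| tau | 0.1 | envelope deviation tolerance (beta units) |
| q_low/q_high | 0.05 / 0.95 | envelope quantile levels |
| threshold | 0.05 | detection/masking p-value cut |
| pool_beta_window | on | restrict pool to intermediate-beta readings |
| include_oob (pool) | off | add OOB maxima to the pool |
| include_controls | on | add negative controls to the pool |

`nbins`/`min_per_bin` are chosen so a few-hundred-thousand-probe array
gets well-populated fine bins while a 2,000-record simulation still bins
sensibly. `tau` parameterizes the otherwise qualitative notion of a bin
"deviating"; it is reported in every run's metadata.

## The signal simulator

The generator produces ground-truthed SignalSets reproducing the
phenomena that matter to detection calling. Per probe:

* **Population truth.** beta_true is 0 or 1 with probability
  (1 − frac_intermediate)/2 each, otherwise uniform(0, 1)
  (frac_intermediate = 0.2).
* **Allelic realization.** k ~ Binomial(2·n_cells, beta_true),
  beta_realized = k / (2·n_cells). Single cells therefore read 0, 0.5 or
  1 — the allelic dichotomization seen in few-cell methylomes.
* **Capture/dropout.** captured_copies ~ Poisson(capture_rate ·
  input_scale · copy_multiplier · gc_factor), with capture_rate = 25 at
  saturating input, copy_multiplier 1 / 10 / 200 for single-copy,
  high-copy-TE and mitochondrial probes (mtDNA is present at hundreds of
  copies per cell), and gc_factor = 1 + 0.05·(n_C − mean n_C) clipped at
  0.01 (GC-rich probes capture better; n_C is the probe C-count, uniform
  on 5..25).
* **Amplification.** Foreground F = captured_copies · signal_per_copy ·
  lognormal(0, 0.3), with signal_per_copy = 2000. The large per-copy
  signal encodes that whole-genome preamplification drives any captured
  locus to near-saturation: dropout, not graded dimming, is how low
  input manifests. F splits as F·beta_realized (M) and
  F·(1 − beta_realized) (U).
* **Background.** Per-channel Gamma(shape 4, mean 250) added to each
  allele read. Background betas are then ≈ Beta(4, 4): centred at 0.5
  with a 5–95% spread of ≈ 0.58, a realistically wide envelope (any
  right-skewed positive background gives the same qualitative geometry).
* **Out-of-band reads.** OOB values are background-shaped but
  scale-inflated by (1 + oob_offtarget), oob_offtarget = 1, whenever any
  template is present. This models the fact that the allele-flipped bead
  of an Infinium-I probe still hybridizes its locus and off-target
  amplified DNA, so real OOB intensities sit above negative controls
  (which use scrambled sequences and stay at optical background). This
  is the feature that makes an OOB-based null conservative on low-input
  data and is a precondition for the rescue behaviour; shape-preserving
  scaling keeps OOB betas distributed like background betas, so joint
  binning is unaffected. At input_scale = 0 (no template) OOB reverts to
  pure background.
* **Controls.** 400 negative controls per channel, pure background.

Randomness: beta_true is drawn from a substream keyed only by the
configuration seed, so all samples simulated under one configuration
share population truth (needed for cross-sample comparisons); per-sample
draws are keyed by (seed, sample index). Outputs are deterministic for a
fixed manifest order.

### What the simulator does not model

Bead-level replicates, dye bias and between-channel intensity asymmetry,
bisulfite-conversion failure, FFPE degradation, spatial/chip effects,
cross-hybridization structure beyond the scalar OOB inflation, and
probe-specific affinity beyond the C-count factor. Tests passing on this
generator show the algorithm's logic is correct under the stated
generative assumptions; they do not certify performance on real arrays.

## Numerical and degenerate-input choices

* beta = M/(M+U) with no pseudo-count; M + U = 0 gives a missing beta
  ("no reading"), never 0.5 ("background-centred reading").
* log2(total + 1) admits zero totals without −inf.
* Quantiles: linear interpolation between order statistics; the
  convention matters on small bins and is fixed package-wide.
* ECDF ties: counted by ≥ with no midrank correction; the add-one form
  keeps p > 0 so −log10 p is always finite.
* All-equal totals collapse to a single bin; a single-bin envelope is an
  array-wide failure by definition.
* Binarization is strict (beta > 0.5 is 1, 0.5 is 0); F1 excludes probes
  undefined in either vector and treats the reference's 1-calls as truth.
* Odds ratios use Haldane's +0.5 only when a cell is zero; FDR is
  Benjamini–Hochberg; Spearman uses midranks.
* Normal-tail p-values are clipped at 1e-300 to stay in (0, 1].

## Known limitations

* The detected fraction of background-only probes under the default
  (windowed) pool runs ~30% above the nominal threshold (see step 5);
  use `pool_beta_window=False` where exact null calibration matters more
  than sensitivity.
* Merging N few-cell methylomes estimates beta_true with binomial
  sampling error sd = sqrt(b(1−b)/(2·N·n_cells)); at 200 single cells
  that is up to 0.025, so individual intermediate-methylation probes can
  deviate from truth by more than 0.05 even though the vast majority
  (measured ≈ 99.6%) land within it.
* pOOBAH here follows the published description (per-channel OOB ECDF,
  min over channels for type II); exact parity with any particular
  reference implementation's p-values is not claimed.
* Problem sizes used by the test-suite and the reproduction script
  (20,000-probe arrays, 2,000-probe merging cohorts, 50 onset
  replicates) are desk-scale choices that keep every property measurable
  in seconds while leaving binomial/quantile noise well below the
  asserted margins.
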