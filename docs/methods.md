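# Methods

This note documents the models, numerical choices and known limitations of
the package, stage by stage.

## Isotope envelopes and pair geometry

Peptide elemental compositions are residue sums (standard amino-acid table
from pyteomics) plus one water and the recognized modification deltas:
methionine sulfoxide (+O, carrying the ¹⁶O/¹⁸O species label), N-terminal
acetylation (+C₂H₂O) and carbamidomethyl-cysteine (+C₂H₃NO). Envelopes are
*aggregated* (unit-mass binned) isotopologue distributions computed by
convolving per-element natural isotope distributions, using exponentiation
by squaring with truncation at index K (default K = 6, covering >99.9% of
envelope mass for tryptic peptides). Truncating intermediates is exact for
the retained bins because neutron offsets are nonnegative. The elemental
abundance table (IUPAC/NIST values) is pinned as a plain-text package
resource (`data/isotope_abundances.tsv`).

The heavy (¹⁸O sulfoxide) species has the same elemental composition as the
light species, so one envelope describes both. Its m/z grid is offset by
2.004246/z. The 2.5 mDa mismatch between two ¹³C spacings (2 × 1.00335 Da)
and the label offset is treated as unresolved: at a resolving power of
120,000 (at m/z 200) the light M+k+2 and heavy M+k centroids coalesce. The
heavy envelope is therefore modeled as the light envelope shifted by exactly
two isotopologue positions, which is what makes the channel-mixing weights
simple envelope sums with closed-form inversion.

## Trace extraction and elution fitting

Extraction takes, per scan and per target m/z, the most intense centroid
within the ppm tolerance (default 10 ppm); scans without a match contribute
zero. The most-intense rule is standard XIC practice and keeps extraction
deterministic. The retention-time window is the evidence retention time
± `rt_halfwidth` (default 1.0 min).

Elution profiles are fitted in the retention-time dimension with 1..3
Gaussian components by bounded least squares; the component count is chosen
by BIC (fitting a fresh component seeded at the residual maximum each
round), and the component whose mean is nearest the predicted retention
time is selected. Fitting only *delineates* the peak — quantification uses
the raw trace intensities inside the selected component's ±3σ bounds, since
the downstream slope regression is defined on observed summed intensities.
Traces with fewer than five nonzero scans yield an invalid fit rather than
an exception.

Consecutive isotopologues are linked into a cluster only while every
adjacent pair of traces has cosine similarity ≥ 0.6 (inclusive); traces
after the first failing link are discarded, so accepted indices always form
a contiguous run from the monoisotopic peak.

## Ratio estimation and overlap correction

Per scan, the light channel sums the accepted light-species isotopologues
with index in {0, 1} — the only positions the shifted heavy envelope cannot
reach — and the heavy channel sums all accepted heavy-species positions.
The raw ratio is the OLS slope of light on heavy with a free intercept
(robust to a constant baseline); R² from the same regression gates validity
at ≥ 0.8. Fewer than five scans with both channels positive invalidates the
pair ("insufficient points"). When the light channel is exactly constant
(noiseless pure-heavy data) R² is defined as 1 for a perfect fit, 0
otherwise.

The mixing model

```
obs_light = w_LL·L + w_LH·H        obs_heavy = w_HL·L + w_HH·H
```

uses weights computed from the peptide's own envelope over the index sets
*actually accepted* into each cluster, so cosine truncation keeps the
correction consistent with the summed signal. Inversion gives
ρ = L/H = (r·w_HH − w_LH)/(w_LL − r·w_HL), clamped to [0, ∞); a vanishing
denominator is the pure-light limit and maps to MOS = 1. Finally
MOS = ρ/(1+ρ).

Reagent isotopic impurity is *not* corrected by default — the labeling
reagent's stated impurity bound (≤10%) is a property of the chemistry, and
correcting for an unknown actual impurity would be speculative. The
simulator exposes a `heavy_purity` parameter so the effect can be studied
in the forward direction.

## Titration model

The carrier-mixing model `MOS_ij = t_i + (1−t_i)·MOS_invivo,j` is the
unique linear model consistent with the variable definitions: a fully light
carrier at fraction t contributes stoichiometry t when in vivo oxidation is
absent, and a fully oxidized site (MOS = 1) is a fixed point at every t.
The single parameter is estimated by bounded nonlinear least squares on
[0, 1], seeded with the exact linear least-squares solution (the model is
linear in the parameter; the bounded solver adds only the constraint).
The standard error comes from the residual-scaled fit covariance. NRMSE is
the residual RMSE divided by the mean observed MOS (range normalization is
available as an option); estimates pass QC at NRMSE ≤ 0.2. Observations
are not clipped to [0, 1] before fitting — only the parameter is bounded —
though a `clip_observations` flag exists for sensitivity checks.

Filters before fitting: cysteine-containing peptides are dropped entirely,
and a peptide needs ≥ 7 valid values out of the 12 runs in *each* age group
(2 titration points × 2 technical × 3 biological replicates). Estimates are
produced per age group and for the pooled 24-run "interage" grouping.

## Statistics

**Oxidation-prone methionines.** Interage estimates are converted to
effects = distance from the global median of the filtered set; standard
errors are the titration SEMs (floored at 10⁻⁶ to keep likelihoods finite).
The adaptive shrinkage model is a point-null plus half-uniform mixture,
π₀δ₀ + Σ πₘ·U(0, bₘ), with only positive effect support, over a geometric
grid from SE_min/10 to 2·max|effect| at ratio √2. Weights are fitted by EM
with uniform initialization (tolerance 10⁻⁸, cap 2000 iterations; the
likelihood is flat in overlapping components, so the weight vector itself
is not identifiable — the per-record posteriors, which are what we use,
are stable). Under this prior the local false-sign rate equals the
posterior null responsibility; q-values are the running mean of sorted
rates, with monotonicity enforced, and significance is q ≤ 0.01. Note that
posterior means of records near zero are pulled *upward* toward the
positive prior mass — shrinkage toward zero holds only for effects clearly
above the noise floor; this is inherent to one-sided priors.

**Age contrasts.** Per peptide, t = (MOS_old − MOS_young)/√(SEM_old² +
SEM_young²), with Welch–Satterthwaite degrees of freedom built from the
per-group titration residual counts (n−1 each, floored at 3), and
Holm–Bonferroni step-down adjustment (statsmodels) across peptides.

## The simulator, and what passing tests do and do not show

The simulator emulates: shared light/heavy envelopes at the correct m/z
with the 2.004246 Da offset; Gaussian elution (default σ = 0.03 min on a
2-min scan window at 1 s cycle time — a scaled-down stand-in for a 90-min
gradient); carrier mixing t + (1−t)·MOS_true; heavy-reagent impurity;
lognormal multiplicative noise (default σ = 0.01), optional additive
baseline and spurious centroids; and resolution-limited centroid merging
(0.005 Da), which is what physically creates the envelope overlap. The
default in vivo MOS distribution is 90% lognormal (median 0.04, log-σ 0.5)
with a 10% Uniform(0.15, 0.5) oxidation-prone tail, putting the global
median near 0.045 — the few-percent bulk regime expected in post-mitotic
tissue.

Not emulated: retention-time drift across runs, chimeric/interfering
peptides beyond chance m/z collisions, detector saturation, missing
identifications (every simulated peptide has an evidence row in every run),
and MS2 spectra. Passing tests therefore demonstrate correctness of the
computation — envelope math, overlap inversion, regression, calibration of
standard errors and false-sign rates under the stated noise model — not
robustness to every pathology of real chromatography.

Problem sizes used by the validation suite: the self-validation benchmark
uses 50 peptides in one run; the end-to-end recovery study uses 72 peptides
(12 per true MOS value in {0, 0.02, 0.05, 0.1, 0.3, 0.5}) across the full
24-run design, where single-component elution fitting is configured since
each simulated trace contains one analyte. The SEM calibration ratio there
is mean SEM divided by the pooled within-truth empirical SD: pooling avoids
the boundary artifact at MOS_true = 0, where the [0,1] parameter bound
censors the empirical spread.

## I/O notes and limitations

mzML/mzXML reading is MS1-only and requires centroided input (profile data
is rejected with a clear message); 32/64-bit floats with zlib or no
compression are supported, but vendor-specific extensions and numpress are
not. The mzML writer emits minimal standards-conformant documents
(uncompressed 64-bit arrays) and round-trips exactly through the reader.
Evidence tables follow the common search-engine export dialect (Sequence,
Modifications, Charge, m/z, Retention time, Raw file, optional Score /
Retention length); charges outside 2–5 are skipped, duplicate
(sequence, charge, run) rows keep the highest score. All thresholds live in
`PipelineConfig`, which round-trips losslessly through JSON.
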