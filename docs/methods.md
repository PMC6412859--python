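# Methods

## Scope and data model

The package implements the full analysis chain of a two-color miRNA
microarray study with qRT-PCR validation and MTI-network hub analysis.
All tabular data are tidy TSV/DataFrames: array foreground intensities
(`probe_id, array_id, channel, foreground` with channels `sample_Hy3`
and `reference_Hy5`, plus `array_id → group` metadata), Cp tables
(`sample_id, group, assay, cp`, empty cp = undetermined), and MTI
source tables (`mirna, target, score`, one file per source dialect).
No real measurements ship with the package beyond a small published
group-level example panel (eight miRNAs, their validation table, four
hub genes with regulators, primer efficiencies, and two body-weight
summaries); raw-scale inputs are always simulated.

## Statistical primitives

All group comparisons use the two-tailed unequal-variance (Welch)
t-test with Welch–Satterthwaite degrees of freedom and exact
t-distribution p-values — group sizes are 2–6 throughout, so no normal
approximation is acceptable. A summary-statistic form
(`welch_t_test_from_summary`) computes the identical quantities from
mean ± SD and n, allowing printed tables to be tested. Degenerate
zero-variance-in-both-groups inputs return p = 1 for equal means and
p = 0 otherwise, flagged as degenerate; the convention is ours — the
situation does not arise in continuous data. No multiple-testing
correction is applied anywhere, deliberately matching the workflow the
package reimplements. The signed fold change is sign(L)·2^|L| with
L = 0 ↦ +1.0; the +1 choice keeps continuity with "no change means
ratio 1" rather than mapping to 0 or −1.

## Normexp background correction

Observed foreground is modeled as X = B + S, B ~ N(μ, σ²),
S ~ Exp(mean α). The correction replaces x by
E[S | X = x] + offset, the mean of a normal N(μ_sx, σ²) truncated to
S > 0 with μ_sx = x − μ − σ²/α. The hazard ratio φ/Φ is evaluated as
exp(logpdf − logcdf) so the result remains positive and strictly
increasing even for spots far below the background mean. The default
offset is 10.

Parameter estimation offers two methods:

* **moments** — α = (m₃/2)^{1/3} from the third central moment (the
  normal part contributes none), σ² = var − α², μ = mean − α, clamped
  to positivity: σ² ≤ 0 is floored at 10⁻⁴·var and μ < 0 is clamped to
  0 with α refit to the mean.
* **mle** (pipeline default) — maximizes the exact convolution
  likelihood (Nelder–Mead on (μ, log σ, log α), moment estimate as the
  start).

The pipeline default deviates from the simpler moments choice for a
measured reason: at a few hundred probes with σ ≪ α the third moment
carries ~30% relative error in α, and the leftover variance is dumped
into σ — corrected dim spots are then shrunk toward a large pseudo-
background and all log-ratios compress, which we observed to halve
recovered effect sizes on roughly a quarter of simulation seeds. The
likelihood pins σ through the sharpness of the lower edge of the
intensity distribution and is stable at the same scale. Note that even
at n = 10⁴ the MLE of σ retains ~±10% sampling spread when σ/α ≈ 0.03;
σ is intrinsically the hard parameter of this model.

## Lowess normalization

M = log2(sample/reference) is regressed on A = (log2 sample +
log2 reference)/2 by locally weighted linear regression (tricube
weights) and the fit subtracted. Defaults: span 0.3, 3 robustness
iterations — a standard choice for MA-plot normalization at a few
hundred spots. If all A coincide the fit is undefined and mean(M) is
subtracted instead. Two practical properties guide the tests: the
residual trend after normalization scales with the bias curvature
within a window (a span matched to the bias wavelength removes a
0.4-log2 bias to < 0.05), and re-normalization perturbs points by
roughly the noise-to-window ratio, so strict per-point idempotence
holds only for locally linear trends at modest noise.

## Differential expression

Per array, the normalized sample-channel log2 intensity is M′ anchored
at the probe's mean A; with a common reference pool on every array,
between-array differences of this quantity equal differences of
normalized log-ratios. The reported effect is the mean of all
(neuropathy array × control array) pairwise log2 differences — 2×2 = 4
comparisons in the study design — while the p-value comes from the
Welch test on the per-array normalized intensities grouped by
treatment. The two statistics deliberately mirror the two printed
columns of such studies (a cross-pair average effect, a group-level
test). Tiers: *significant* = p < 0.05 and |mean| > 0.6; *candidate* =
magnitude only; detection requires the corrected sample intensity to
exceed the array's 5th percentile (configurable) on at least half the
arrays. The detection rule is a stand-in — the real scanner/software
criterion behind published "detectable" counts is not public, which is
also why no detected-probe count is treated as a reproducible result.

## qRT-PCR quantification

miRNA group changes use raw per-sample Cp differences by default
(mean log2 change = −ΔmeanCp, lower Cp = more template); a reference
assay can be configured. An assay is *detected* only with ≥ 2 amplified
samples per group within the 45-cycle protocol. Abundance classes use
the ΔCt to an abundant anchor miRNA with strict bounds: Δ < 6 high,
Δ > 10 low, boundaries intermediate. Target mRNA levels use 2^−ΔΔCp
normalized to a reference gene, with the ΔΔCp anchored at the
*arithmetic mean* ΔCp of the control group (standard Livak practice;
the control geometric mean level is then exactly 1). The
efficiency-corrected variant replaces base 2 by per-assay efficiencies
E ∈ (1, 2] (Pfaffl form with per-assay control-mean calibrators); with
E = 2 it reduces to the base-2 method exactly. Group tests run on
linear levels by default (ΔCp scale available), and reconciliation
marks a miRNA *confirmed* when qPCR is detected, significant at the
same Welch p < 0.05, and direction-concordant with the array; detected
but non-significant results are counted as unconfirmed and flagged.
The final consensus direction follows qPCR where it is detected and
significant, the array otherwise.

## MTI integration and hubs

Records are kept by union across sources — published hub networks
contain single-source edges, so intersection would be wrong. Score
filters: higher-is-better predictions kept iff score > 80.0,
more-negative-is-stronger predictions kept iff score < −1.2 (boundary
values removed in both dialects, exactly as the thresholds are
printed); validated records are exempt from score filtering — an
implied, not stated, behavior of the original integration, flagged
here as configurable by simply not assigning scores to that dialect.
miRNA identifiers match case-insensitively with mature-arm suffixes
(-3p/-5p) required to match exactly; a species tag is carried but not
enforced by default. Hub degree counts *distinct regulator miRNAs*,
never supporting records. Direction prediction defaults to unanimity
(all regulators down → target up; any mix → ambiguous); a majority
rule with configurable fraction exists but is untested by any
published case, which is exactly why it is not the default. Exports:
node/edge TSVs (deterministically sorted), Cytoscape SIF, and GraphML
that round-trips through the provided reader.

## Synthetic data generators

Each generator is a pure function of its config (explicit seed, no
global state) and returns a truth object sufficient to score every
downstream stage.

**Arrays.** Per probe, one baseline signal is drawn from Exp(α) and
shared across arrays and channels, so the across-probe marginal obeys
the normexp model the correction assumes; planted probes' baselines
are floored at 0.2·α (memoryless truncation) so the effects under
study are not parked below the detection limit. Per array and channel
the log2 abundance receives N(0, sd) replicate noise — 0.05 for the
sample channel (distinct pooled RNA per array), 0.02 for the common
reference pool (technical only) — the planted group effect (sample
channel of treated arrays), and, on the sample channel, a smooth
sinusoid-plus-trend dye bias (amplitude 0.4 log2) evaluated at the
spot's *observed* abundance against a fixed experiment-wide intensity
anchor; the bias is large enough that skipping lowess visibly corrupts
DE calls, which the tests use as a negative control. Background
N(100, 15²) is added and negatives floored at 0. Defaults: 300 probes,
2 arrays per group.

The noise defaults are at the clean end of plausible for pooled
technical hybridizations, chosen so that planted effects ≥ 0.75 log2
are reliably selected at the 0.6 threshold in a 2-vs-2 design. One
limit is worth stating plainly: a planted effect of 0.63 sits 0.03
log2 units above the threshold, and no achievable array precision
makes its selection reliable (that would need a total log2 error SD
around 0.01); recovery guarantees therefore apply to direction and
magnitude, and to selection only outside that margin.

**Cp tables.** Cp = baseline − effect·[treated] + per-sample loading
offset (shared across assays; what reference normalization removes) +
N(0, sd_Ct), with reference assays given their own stability noise and
a hard 45-cycle ceiling recorded as undetermined. Defaults: 6 samples
per group, sd_Ct 0.15.

**MTI sources.** Planted hubs receive ≥ min-degree interactions with
threshold-passing scores spread randomly across the three dialects;
decoys receive at most two passing interactions, plus (with
probability 0.4) sub-threshold ones that would promote them to hubs if
the score filter were skipped — a second negative control.

What the generators do **not** emulate: probe sequence effects and
cross-hybridization, spatial array artifacts, heteroscedastic or
heavy-tailed Cp noise, amplification-curve shapes, hierarchical
biological variance (it is folded into the per-channel/per-sample
SDs), and the composition of real MTI databases. Passing recovery
tests therefore demonstrates correctness of the algorithms under the
stated generative assumptions, not performance on real arrays.

## Pipeline

`run_pipeline` executes simulate-arrays → DE → simulate-qPCR →
reconcile → simulate-MTI → network/hubs → simulate target mRNA ΔΔCp →
concordance, writing each stage's TSV (with a config-hash header)
before the next stage runs, and derives per-stage seeds as fixed
offsets from the run seed. Default planted conditions are the example
panel's eight array effects and validation-table qPCR effects (one
assay undetectable), four planted hubs of degree 3 among 200 decoys
regulated by the down-called miRNAs, and 1.8-fold (log2 0.85) planted
increases for hub genes measured against a stable reference gene. A
defaults run completes in a few seconds on one CPU. Numeric output is
rounded only at serialization; full precision is kept internally.
Failure classes map to distinct CLI exit codes (2 missing input, 3
malformed table, 4 infeasible configuration).

## Known limitations

* The pairing scheme behind the "4 parallel comparisons" design is
  all-pairs across groups; a paired scheme would need explicit array
  pairing metadata that the data model does not carry.
* Abundance classification is validated on synthetic Cp values only;
  no per-miRNA ΔCt reference table is bundled.
* The moments estimator for normexp is retained for its closed form
  but should not be used below ~10⁴ spots when background variance is
  small relative to signal (see above).
* Network analysis treats MTI sources as given tables; no live
  database querying or sequence-based target prediction is performed,
  and the literature-driven narrowing of hub lists to a few genes is
  represented only as a configurable gene list.
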