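# Methods

## Scope and data model

The pipeline starts from a finished LC–MS feature table: a samples ×
features matrix of non-negative intensities with per-sample metadata
(catecholamine dose in µM, exposure time in h, donor, batch). Peak
picking, retention-time alignment, internal-standard normalization and
annotation are upstream concerns and out of scope. The companion inputs
are isotopologue abundance vectors per metabolite, stress-test (OCR/ECAR)
cycle series with phase labels and cell counts, and media concentration
time courses with culture volume and cell counts.

## Normalization and fold changes

Quantile normalization is applied across **all** samples jointly (it is
the batch remedy itself, not a within-batch step): each sample's sorted
intensity vector is replaced by the across-sample mean of sorted vectors;
tied values receive the mean of the reference values at their tied ranks.
This removes any monotone per-sample distortion, including the per-donor
multiplicative offsets the generator plants. Note a small-table caveat:
with few features, rank-stable features become exactly constant across
samples after normalization; the profile-recovery analyses therefore
compute fold changes on the raw simulated table, where normalization has
nothing to remove (the generator applies no batch offset to fold-change
ratios).

log₂ fold changes compare each (dose, time) condition mean — pooled across
donors — against the dose-0 mean at the same time point. The study design
does not fix a per-donor pairing rule, so pooled means are used; whether
to average per-donor ratios instead is a genuinely open choice and is
recorded here as the package's decision. A pseudo-intensity (default: half
the smallest nonzero value in the table) keeps ratios finite; with it set
to zero, the transform is exactly antisymmetric under swapping treated and
reference.

## Dose-responder selection

Doses are encoded ordinally (0, 1, 2, 3 for 0, 0.5, 5, 50 µM) by default:
the doses are decade-spaced with a zero, and raw-scale correlation would
be dominated entirely by the 50 µM point. Raw and log₁₀(dose + δ)
encodings are selectable. Correlation and regression are computed on
log₂(intensity + pseudo) across all samples of a time point, matching the
log-linear dose–response model the selection is meant to detect.

A feature is selected when, at the early **or** late time point, all of
the following hold: max |log₂ FC| over treated doses > 1; |Pearson r|
against the encoded dose > 0.8 with p < 0.05; and a significant OLS slope
(two-sided Wald test, p < 0.05). The correlation gate uses |r| because
dose-responders include depleted metabolites (r near −1); a signed gate
could never select them. Both the correlation and regression gates are
applied conjunctively; for simple regression the two p-values coincide
mathematically, so the conjunction is a safeguard rather than a second
filter. All thresholds are configuration-exposed. No multiple-testing
correction is applied by default (none is part of the original selection
rule); selection is monotone in the thresholds by construction.

Selection counts on real data (e.g. "46 of 1230 features") are
data-dependent outcomes, not targets; the package's benchmark is recovery
of planted responders on synthetic data.

## Temporal clustering

Selected features' profiles — log₂ FC over the treated (dose, time)
conditions — are clustered agglomeratively under cosine distance
(1 − cosine similarity) with complete linkage, delegating to
`scipy.cluster.hierarchy.linkage` (deterministic for a given row order;
scipy's ordering resolves distance ties). Cosine distance groups features
by the *shape* of their response, not its magnitude. The dendrogram is cut
at each k in a scan range (default 2 … min(12, n−1)), the Davies–Bouldin
index (mean over clusters of the worst ratio of summed within-cluster
scatter to centroid separation, Euclidean geometry) is computed per cut,
and the k minimising it wins; ties break toward smaller k. Coincident
centroids make the index diverge and are reported as +inf with a warning.

## Isotope arithmetic

Natural-abundance correction assumes independent binomial occurrence of
the heavy isotope (¹³C: 0.0107, ¹⁵N: 0.00364) at each unlabelled position
— a single-element, low-resolution model appropriate for qTOF data. The
convolution matrix has entries C(n−j, i−j)·a^(i−j)·(1−a)^(n−i); the
measured vector is deconvolved by non-negative least squares (plain
inversion can produce negative fractions on noisy data) and renormalised.
A fit residual above 1e-6 warns with the residual value.

Mean enrichment is E = Σ i·mᵢ / n. The theoretical maximum under a design
is E_max = f·π·(expected labelled atoms)/(product atoms), with tracer
fraction f, purity π and the atom-transfer expectation averaged over
biochemical routes. Two presets ship:

* **Lactate from [1,2-¹³C₂]glucose**: glycolysis splits the hexose into
  one doubly labelled and one unlabelled triose, so the expectation is 1
  of 3 carbons; with f = 0.5, π = 0.99 this gives E_max = 16.5%.
* **Glutamate at complete TCA turnover**: acetyl-CoA from pure tracer
  glucose is 50% M2 / 50% M0 (0.5 labels per carbon), and at complete
  turnover every glutamate carbon equilibrates to the acetyl-CoA per-carbon
  enrichment, giving 2.5 of 5 carbons and E_max = 25% at f = 0.5. A
  fixed-point turnover iteration in the test suite confirms the 0.5
  per-carbon limit.

The two reference values treat purity differently (16.5% folds π in; 25%
does not), so whether π is applied defaults per preset and is overridable.
Fractional contribution is c = E/E_max, clipped to [0, 1] with a warning
above 1. When a fraction φ of the measured pool predates labelling, the
newly synthesised material is enriched at E/(1−φ), so
c = (E/(1−φ))/E_max; φ is a required user input — it depends on how much
metabolite the medium contained at time zero and is not derivable from the
isotopologue data alone.

The pentose-phosphate split uses lactate M1/M2 under [1,2-¹³C₂]glucose:
oxidative PPP decarboxylates the labelled C1, converting would-be M2
lactate into M1. The default estimator is the pentose-cycle form
PC = (m1/m2)/(3 + m1/m2); the naive ratio m1/(m1+m2) is retained for
comparison since small observed splits (~2%) cannot discriminate between
the variants.

## Bioenergetics and exchange rates

A stress-test run has 6 basal cycles then 3 cycles after each injection
(oligomycin, FCCP, rotenone + antimycin A). Basal values are always the
mean of the basal cycles; post-injection phases collapse to one value by
the mean of their 3 cycles (default; 'last' and 'extremum' are options —
the mean is the lowest-variance summary and the choice is not fixed by the
assay). Metrics per well, normalised to its cell count: ATP-linked =
basal − oligomycin; maximal = FCCP plateau (non-mitochondrial OCR **not**
subtracted by default, matching the raw-ratio convention of the reference
fold changes; a flag subtracts it); non-mitochondrial = rot/AA plateau;
proton leak = oligomycin − non-mito; spare = maximal − basal; ATP
fraction = ATP-linked / basal. By these definitions
basal = ATP-linked + leak + non-mito exactly. A maximal below basal is a
warning, not an error (real runs do misbehave). Condition profiles are
means of per-well metrics; group comparisons use the Mann–Whitney U test
(exact null distribution when both groups have ≤ 8 observations without
ties, otherwise the tie-corrected normal approximation).

Exchange rates come from endpoint concentrations:
rate = ΔC·V / (N̄·Δt) in µmol·(10⁶ cells)⁻¹·h⁻¹, positive for secretion.
N̄ is the arithmetic mean of the start/end cell counts — cultures grow
over 24 h and a single mid-experiment count convention is not otherwise
fixed; with constant cell numbers the estimator inverts the generator
exactly.

## Synthetic data

The generator's defaults are the study design: doses (0, 0.5, 5, 50 µM),
times (0, 4, 24 h), 3 donors (one sample per design cell), 500 features
with 40 planted responders. Planted responders follow seven temporal
archetypes, encoded as (early, late) direction pairs: transient-down
(down at 4 h, rebound by 24 h — the largest class), sustained-up,
up-then-down, down-then-up, early-up, late-down, late-up, with default
mixing weights (0.25, 0.20, 0.15, 0.15, 0.10, 0.08, 0.07) reflecting that
ordering. The planted log₂ FC ramps linearly with the ordinal dose index,
reaching the configured effect size (default 2) at the top dose, so
responder magnitude is monotone in dose by construction.

Intensities are baseline × 2^(planted lfc) × donor offset × noise, with
lognormal feature baselines (ln-mean 11, ln-σ 1 — spanning the dynamic
range typical of LC–MS features), multiplicative lognormal measurement
noise (σ = 0.1) and a per-donor multiplicative offset (σ = 0.1) shared
across features, which doubles as the batch effect. The noise and donor
magnitudes are package defaults chosen as plausible for this data type —
no per-feature variance components were available to copy — and are fully
user-tunable.

The isotopologue generator draws the true vector as Binomial(n, c·E_max)
— correct in mean enrichment by construction, though real positional
isotopomer distributions (e.g. lactate's M2-heavy pattern) are not
binomial — then convolves with natural abundance and applies optional
multiplicative noise. The stress-test generator scales per-phase means by
condition multipliers; the media generator integrates per-cell rates over
an exponential cell-count trajectory in closed form.

Every generator draws from its own `numpy.random.default_rng` stream
seeded from its config, so identical configs give bit-identical outputs
and each stage is reproducible in isolation.

What the generator does **not** emulate: raw spectra and chromatographic
peaks, retention drift, feature-feature correlations (pathway structure),
heteroscedastic per-feature variances, missingness, and donor-by-feature
interactions. Passing recovery benchmarks on this generator therefore
demonstrates correctness of the statistical machinery under the stated
noise model, not performance on the full messiness of real LC–MS data.

## Problem sizes and benchmark conditions

The recovery benchmarks run at the design scale: responder selection on
500 features / 40 responders / 3 donors (noise σ = 0.1, effect size 2),
and cluster-number recovery on 49 planted profiles (7 per archetype) over
50 seeded replicates with the number of clusters scanned over 2–12. Both
complete in seconds on one CPU.

## Known limitations

* The correction model is single-element and resolution-agnostic; isobaric
  interference and multi-element corrections are out of scope.
* The atom-transfer presets are endpoint idealisations (pure glycolysis;
  complete TCA turnover); partial turnover requires a flux model.
* Fold-change and selection operate on condition means; donor-level mixed
  models are not implemented.
* The Davies–Bouldin criterion uses Euclidean geometry on profiles that
  were clustered by cosine distance; this mirrors common practice but
  mixes metrics, and very elongated clusters can bias the chosen k.
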