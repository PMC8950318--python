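# catechoflux

Analysis pipeline for the metabolic response of endothelial cells to
sustained catecholamine stimulation. Human endothelial cells (e.g. HUVECs)
exposed to equimolar adrenaline/noradrenaline mixes (0, 0.5, 5, 50 µM)
remodel their metabolism over hours; this package implements the
computational side of such a study end to end:

* **Dose–response feature selection** from untargeted LC–MS feature tables:
  quantile normalization across samples, log₂ fold changes against
  dose-0 same-time references, and a joint gate — |log₂ FC| > 1, |Pearson
  r| > 0.8 (p < 0.05) against the encoded dose, and a significant OLS slope
  (Wald test, p < 0.05) — applied at the early (4 h) or late (24 h) time
  point.
* **Temporal clustering** of the selected features' fold-change profiles:
  agglomerative hierarchical clustering with cosine distance and complete
  linkage, cut at the number of clusters minimising the Davies–Bouldin
  index.
* **Stable-isotope arithmetic** for [1,2-¹³C₂]glucose and [¹⁵N₂]glutamine
  tracing: natural-abundance correction by non-negative least squares,
  mean enrichment E = Σ i·mᵢ / n, theoretical maximum enrichments under a
  tracer design and atom-transfer model, fractional contributions
  c = E/E_max (optionally corrected for a pre-existing pool), and the
  pentose-phosphate split ratio from lactate M1/M2.
* **Bioenergetics**: per-cell OCR/ECAR metrics (basal, ATP-linked, maximal,
  proton leak, non-mitochondrial, spare capacity, ATP fraction) from
  mitochondrial stress-test cycle series, and per-cell extracellular
  exchange rates (positive = secretion) from media time courses.
* **A synthetic-data generator** that emulates the full experimental design
  with planted ground truth (responder sets, seven temporal archetypes,
  isotopologue vectors, stress-test runs, media time courses), so every
  stage is testable without any external data.

The intended users are metabolomics / cell-metabolism researchers who have
a finished feature table (peak picking, alignment and internal-standard
normalization already done upstream) and want a reproducible, tested path
from intensities to dose-responders, cluster dynamics, enrichments and
rates.

## Worked example

`examples/01_dose_response_selection.py` simulates the full design
(4 doses × 3 times × 3 donors, 500 features, 40 planted responders,
lognormal noise σ = 0.1) and runs the selection and clustering stages:

```text
simulated 36 samples x 500 features
selected 38 features (sensitivity 0.95, precision 1.00)
optimal partition: k=7 clusters (Davies-Bouldin 0.240)
cluster sizes: {1: 12, 2: 3, 3: 8, 4: 2, 5: 4, 6: 5, 7: 4}
```

38 of the 40 planted responders are recovered with no false positives, and
the Davies–Bouldin scan recovers the seven planted temporal archetypes.
`examples/02_isotope_enrichment.py` walks the isotope algebra:

```text
max lactate 13C enrichment: 16.5%
max glutamate 13C enrichment: 25.0%
glucose->glutamate carbon contribution: 17.92%
glucose->lactate carbon contribution (pool-corrected): 86.7%
simulated c=0.5 lactate: corrected enrichment 8.25% (= 0.5 x 16.5%)
PPP split for m1/m2 = 0.06: {'lee': '1.96%', 'simple': '5.66%'}
```

The 16.5% ceiling is 0.5 (tracer fraction) × 0.99 (purity) × 1/3 (one
labelled carbon per three-carbon lactate, averaged over both trioses of a
[1,2-¹³C₂]glucose); the 25% glutamate ceiling follows from complete TCA
turnover against a 50% M2 acetyl-CoA pool. The remaining examples cover
the bioenergetic metrics, exchange rates and the end-to-end driver.

A thin CLI mirrors the library (`catechoflux simulate|normalize|foldchange|
select|cluster|enrich|bioenergetics|rates|run`); exit codes are 0 on
success, 2 on validation errors, 3 on numerical failures.

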