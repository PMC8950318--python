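"""Isotope-tracing arithmetic: enrichment maxima, contributions, PPP split.

Walks the chain from a measured isotopologue vector to biological
conclusions for the 50:50 [1,2-13C2]glucose feeding design: theoretical
maximum enrichments, fractional contributions (with and without a
pre-existing pool), and the pentose-phosphate split ratio from lactate
M1/M2.
"""

from catechoflux import (
    GLUCOSE_12C2_TRACER,
    GLUTAMATE_FROM_GLUCOSE,
    LACTATE_FROM_GLUCOSE,
    contribution_with_preexisting_pool,
    correct_natural_abundance,
    fractional_contribution,
    mean_enrichment,
    ppp_fraction_all,
    simulate_isotopologues,
    theoretical_max_enrichment,
)

# ceiling on lactate enrichment under the feeding design: 50% tracer, 99%
# purity, 1 labelled carbon per 3-carbon lactate averaged over both trioses
e_max_lac = theoretical_max_enrichment(LACTATE_FROM_GLUCOSE, GLUCOSE_12C2_TRACER)
print(f"max lactate 13C enrichment: {100 * e_max_lac:.1f}%")

# glutamate ceiling at complete TCA turnover (purity not folded in)
e_max_glu = theoretical_max_enrichment(GLUTAMATE_FROM_GLUCOSE, GLUCOSE_12C2_TRACER)
print(f"max glutamate 13C enrichment: {100 * e_max_glu:.1f}%")

# a 4.48% observed glutamate enrichment expressed as a carbon contribution
c = fractional_contribution(0.0448, e_max_glu)
print(f"glucose->glutamate carbon contribution: {100 * c:.2f}%")

# 13.5% lactate enrichment at 24 h, correcting for ~5.7% of the measured
# lactate pool that was already in the media before labelling started
c_lac = contribution_with_preexisting_pool(0.135, 0.0566, e_max_lac)
print(f"glucose->lactate carbon contribution (pool-corrected): {100 * c_lac:.1f}%")

# round trip: simulate a measured vector at known contribution, correct it
v = simulate_isotopologues(GLUCOSE_12C2_TRACER, LACTATE_FROM_GLUCOSE, contribution=0.5)
corrected = correct_natural_abundance(v, GLUCOSE_12C2_TRACER.natural_abundance)
print(f"simulated c=0.5 lactate: corrected enrichment "
      f"{100 * mean_enrichment(corrected):.2f}% (= 0.5 x 16.5%)")

# PPP split from lactate M1/M2 (oxidative PPP turns M2 into M1 lactate)
print("PPP split for m1/m2 = 0.06:", {
    k: f"{100 * val:.2f}%" for k, val in ppp_fraction_all(0.006, 0.1).items()
})
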