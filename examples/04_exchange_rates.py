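"""Extracellular exchange rates from media concentration time courses.

Plants known per-cell glucose-uptake and lactate-secretion rates, integrates
them into media concentrations over 24 h, and recovers the rates.  Positive
rates denote secretion, negative rates uptake.
"""

from catechoflux import exchange_rate
from catechoflux.synthetic import simulate_media_timecourse

planted = {"glucose": -0.0833, "lactate": 0.15, "pyruvate": 0.002}
courses = simulate_media_timecourse(
    planted,
    cells0=1.0e6,
    growth=0.0,
    volume_ml=2.0,
    times=(0.0, 4.0, 24.0),
    initial_concentrations={"glucose": 5.0, "lactate": 1.0, "pyruvate": 0.1},
)

for name, tc in courses.items():
    rate = exchange_rate(tc)
    direction = "secretion" if rate > 0 else ("uptake" if rate < 0 else "no net flux")
    print(
        f"{name:9s} {tc.concentrations_mM[0]:.3f} -> {tc.concentrations_mM[-1]:.3f} mM"
        f"  rate {rate:+.4f} umol/1e6 cells/h ({direction}, planted {planted[name]:+.4f})"
    )
# with zero noise and constant cell number the planted rates return exactly.
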