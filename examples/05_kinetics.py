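"""Relative maximum velocity (relVmax) from kinetic progress curves.

Simulates saturating fluorescence progress curves read at 2-minute
intervals and extracts the maximum sliding-window slope, reported
relative to the reference enzyme.
"""

from resurf.assay import kinetic_relvmax
from resurf.simulate import simulate_kinetics

true = {"wt": 10.0, "variant_a": 7.0, "variant_b": 3.0}
traces, _ = simulate_kinetics(true, noise_sd=1.0, seed=4)

wt_v = kinetic_relvmax(traces[traces.well == "wt"].time_min,
                       traces[traces.well == "wt"].signal)
print("estimated Vmax and relVmax (vs wild type):")
for well, v_true in true.items():
    sub = traces[traces.well == well]
    v = kinetic_relvmax(sub.time_min, sub.signal)
    print(f"  {well:>10s}: Vmax ~ {v:6.2f} (true {v_true:4.1f}), "
          f"relVmax = {v / wt_v:.2f}")
# relVmax ~ 1.0 for the reference and ~ the true velocity ratio for the
# variants; a variant above 0.5 passes the activity QC gate.
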