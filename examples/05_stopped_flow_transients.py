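"""Analyze stopped-flow flavin-reduction transients.

Absorbance decays at 461 nm are simulated for several NADH concentrations,
each fit to a double exponential; the fast-phase rates are then fit to the
zero-intercept hyperbola kobs = kred*S/(Kd + S) to recover the limiting
reduction rate and the substrate dissociation constant.
"""

from nqogate import kinetics, synthetic

spec = synthetic.KineticsSimSpec(
    true_kred=4.8, true_Kd=450.0, slow_phase_rate=0.1,
    slow_phase_fraction=0.08, rng_seed=9)
concentrations = [90.0, 150.0, 250.0, 350.0, 500.0]
traces = synthetic.simulate_traces(spec, concentrations)

points = []
print("per-trace biexponential fits:")
for tr in traces:
    fit = kinetics.fit_biexponential(tr)
    points.append((tr.substrate_concentration, fit.kobs1))
    print(f"  [NADH] = {tr.substrate_concentration:5.0f} uM: "
          f"kobs1 = {fit.kobs1:5.2f} s^-1, kobs2 = {fit.kobs2:5.2f} s^-1, "
          f"fast phase {100 * fit.amplitude_fraction_fast:.0f}% of amplitude")

sat = kinetics.fit_saturation(points)
print(f"saturation fit: kred = {sat.kred:.2f} +/- {sat.se['kred']:.2f} s^-1, "
      f"Kd = {sat.Kd:.0f} +/- {sat.se['Kd']:.0f} uM")
print("  -> kobs1 rises hyperbolically with [NADH] toward kred (truth 4.8),")
print("     half-saturating at Kd (truth 450 uM); the slow ~0.1 s^-1 phase")
print("     is substrate-independent and carries <10% of the amplitude")
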