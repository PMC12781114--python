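"""Fit the ping-pong bi-bi rate law, with and without NADH inhibition.

Initial-rate tables v0/e([NADH], [CoQ0]) are simulated from known
parameters with 1% multiplicative noise, fit jointly as a surface, and the
generating mechanism is identified by AICc + F-test model selection.
"""

from nqogate import kinetics, synthetic

# a wild-type-like enzyme: strong NADH substrate inhibition (Kis = 1.1 uM)
wt = synthetic.KineticsSimSpec(
    true_kcat=11.0, true_Ka=0.4, true_Kb=35.0, true_Kis=1.1,
    nadh_grid=(30., 40., 50., 60., 80., 100.),
    coq0_grid=(30., 50., 70., 100., 150.), replicates=3, rng_seed=7)
data = synthetic.simulate_rates(wt)
print(f"simulated {len(data)} rate measurements "
      f"({data.provenance})")

# relative (1/v) weighting matches the constant-CV noise of initial rates
f1 = kinetics.fit_pingpong(data, weighting="relative")
f2 = kinetics.fit_pingpong_substrate_inhibition(data, weighting="relative")
sel = kinetics.select_model(f1, f2, data)
print(f"model selection: {sel.choice} "
      f"(F = {sel.f_statistic:.1f}, p = {sel.p_value:.2g})")
print(f"  kcat   = {f2.kcat:6.2f} +/- {f2.se['kcat']:.2f} s^-1   (truth 11)")
print(f"  K_CoQ0 = {f2.Kb:6.1f} +/- {f2.se['Kb']:.1f} uM    (truth 35)")
print(f"  K_is   = {f2.Kis:6.2f} +/- {f2.se['Kis']:.2f} uM    (truth 1.1)")
print(f"  R^2    = {f2.r_squared:.4f}")
print("  -> the inhibition model is correctly preferred and the")
print("     parameters recover the truth within their standard errors;")
print("     K_NADH is left out: on this grid it is unidentifiable, as its")
print(f"     huge SE shows ({f2.Ka:.2g} +/- {f2.se['Ka']:.2g} uM)")

eff, se = kinetics.efficiency(f2.kcat, f2.Kb, f2.se["kcat"], f2.se["Kb"])
print(f"catalytic efficiency kcat/K_CoQ0 = {eff:.2e} +/- {se:.1e} M^-1 s^-1")
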