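"""Fit the two-component gamma mixture to one cultivar's grain weights.

Simulates 1500 single-grain dry weights from a known mixture (17.5 %
unfilled grains around 6 mg, filled grains tightly around 25 mg), fits
the five parameters by EM with 20 random restarts, and prints the
recovered parameters next to the truth, the interpretable feature
values, and the boundary analysis. The boundary ratio is the mass near
the inter-peak density minimum relative to the mass near the filled-
grain mode: small values mean filled and unfilled grains are cleanly
distinguishable.
"""

import grainfill as gf

true = gf.MixtureParams.from_values(0.175, 1.5, 4.0, 100.0, 0.25)
sim = gf.simulate_grain_weights(true, 1500, seed=42, cultivar_id="demo")

fit = gf.fit_with_restarts(sim.sample, n_restarts=20, seed=7)
est = fit.params

print(f"cultivar 'demo': {len(sim.sample)} grains, "
      f"log-likelihood {fit.loglik:.1f}, converged={fit.converged}")
print(f"{'':>10} {'p':>8} {'a1':>8} {'b1':>8} {'a2':>8} {'b2':>8}")
print("true      " + "".join(f"{v:9.3f}" for v in true.as_array()))
print("estimated " + "".join(f"{v:9.3f}" for v in est.as_array()))

fv = gf.feature_values(est)
print(f"\nfeature values: mode1={fv.mode1:.2f} mg (unfilled-grain mode), "
      f"skewness1={fv.skewness1:.2f},")
print(f"  mu2={fv.mu2:.2f} mg (filled-grain mean), var2={fv.var2:.2f} mg^2")

ba = gf.boundary_analysis(est)
print(f"\nboundary point {ba.boundary_point:.2f} mg separates the components;")
print(f"  mass within +-0.1 mg of it: {ba.boundary_probability:.2e} "
      f"vs {ba.mode_probability:.3f} at the filled-grain mode "
      f"(ratio {ba.ratio:.4f} -> clearly bimodal)")
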