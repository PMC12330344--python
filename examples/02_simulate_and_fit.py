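"""Simulate one droplet-regime study and refit the generating model.

Generates 10 patients x 250 cells of a two-gene pair whose co-expression
drops from tanh(0.06) pre to tanh(0.06 - 0.20) post, fits the copula
mixed model, and tests the differential co-expression contrast tau1.
"""

from zicoex import FitControl, droplet_preset, fit, natural_scale_rho, simulate, wald

preset = droplet_preset(n_patients=10, cells_per_patient=250)
dataset = simulate(preset, seed=1)
print(f"simulated {dataset.counts.shape[0]} cells from "
      f"{preset.n_patients} patients; zero fractions "
      f"{(dataset.counts == 0).mean(axis=0).round(3)}")

result = fit(dataset.to_pair_data(), control=FitControl())
print(f"converged: {result.converged}  edf: {result.edf:.1f}  "
      f"selected lambda: {result.state.lam.round(1)}")

test = wald(result, "rho.group")
print(f"tau1_hat = {test.estimate:.4f} (truth {preset.tau1}), "
      f"SE = {test.se:.4f}, p = {test.p:.4g}")
r0, r1, dr = natural_scale_rho(result)
print(f"rho(group 0) = {r0:.4f}, rho(group 1) = {r1:.4f}, "
      f"|delta rho| = {dr:.4f}")
print("A significant tau1 means the two genes' correlation genuinely "
      "differs between the groups, beyond patient-level variation.")
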