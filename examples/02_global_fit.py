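"""Global dispersion fit with Monte-Carlo errors on a synthetic dataset.

Generates one four-probe R1rho dataset at 2% intensity noise from a
known truth (pES = 6.2%, kex = 453 s^-1), reduces the decays to R1rho
values, fits all probes globally with shared exchange parameters, and
reports Monte-Carlo uncertainties.
"""

from rnaexcite import fit_r1rho_global, gen_r1rho_dataset, mc_errors, t1_ground_truth

truth = t1_ground_truth(pES=0.062, kex=453.0, noise=0.02, seed=7)
profiles, truth = gen_r1rho_dataset(truth)

fit = fit_r1rho_global(profiles, seed=7)
fit.errors = mc_errors(fit, profiles, n_mc=50, seed=7)

p = fit.params
print(f"truth      : pES = 6.20 %, kex = 453 s^-1")
print(f"global fit : pES = {100*p.pES:.2f} +- {100*fit.errors['pES']:.2f} %, "
      f"kex = {p.kex:.0f} +- {fit.errors['kex']:.0f} s^-1")
print(f"ES lifetime: {1e3*p.tau_ES:.2f} ms   chi2/dof = {fit.chi2_reduced:.2f}")
print()
print("per-probe chemical-shift differences (ppm, truth 1.0/1.5/2.0/2.5):")
for rid, pf in sorted(fit.probe_fits.items()):
    sd = fit.errors["probes"][rid]["delta_omega_ppm"]
    print(f"  residue {rid}: dw = {pf.delta_omega_ppm:+.3f} +- {sd:.3f}")
print()
print("The shared minor-state population and exchange rate are what the")
print("dispersion experiment determines; per-probe dw values locate each")
print("nucleus's excited-state resonance.")
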