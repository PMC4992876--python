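"""Fit the two-tissue compartment model to a simulated tumor TAC.

Simulates a 2 h, 52-frame acquisition of an intrinsically hypoxic tumor
(MDA-MB-435-like kinetics 1 h post therapy) with low (whole-ROI-level) counting noise,
fits both the irreversible and the reversible model, and prints the
recovered rates, the residual-percentage goodness of fit (epsilon) and the
fitted k4.
"""

from fmisopk import (
    NOISE_LEVELS,
    compare_models,
    default_schedule,
    make_input_function,
    preset_params,
    simulate_tac,
)

schedule = default_schedule()
cp = make_input_function()
truth = preset_params("MDA-1h")
tac = simulate_tac(truth, cp, schedule,
                   noise_sigma0=NOISE_LEVELS["low"], seed=7)[0]

cmp = compare_models(tac, cp)
fit = cmp.irreversible.params

print("        truth   irreversible fit")
for name in ("K1", "k2", "k3"):
    print(f"{name:>4}  {getattr(truth, name):>8.5f}   {getattr(fit, name):>8.5f}")
print(f" w_p  {truth.w_p:>8.5f}   {fit.w_p:>8.5f}")
print()
print(f"epsilon: irreversible {cmp.irreversible.epsilon:.2f}%  "
      f"reversible {cmp.reversible.epsilon:.2f}%  (accepted below 5%)")
print(f"fitted k4 (reversible model): {cmp.fitted_k4:.2e} 1/min")
print()
print("The irreversible model explains the data; with noise the reversible")
print("fit's k4 sits at the noise floor rather than indicating true efflux.")
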