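"""Melting-temperature estimate from a CD ellipticity profile at 222 nm.

Simulates a noiseless thermal melt whose plateau-plus-one-phase-decay curve
crosses its baseline midpoint at 59.92 degC (the apo-protein case), fits the
model, and prints the recovered midpoint; Tm has the closed form
X0 + ln(2)/K for this model.
"""

from pdekit import AssaySimSpec, MeltDataset, fit_melt, simulate_assay
from pdekit.simulate import melt_params_for_tm

params = melt_params_for_tm(59.92, x0=50.0, y0=-10.0, plateau=-1.0)
df = simulate_assay(AssaySimSpec("melt", params=params, sigma=0.0, seed=1))[0]
fit = fit_melt(MeltDataset(df["temp_C"], df["theta222"]))

print(f"Tm = {fit.Tm:.2f} degC (midpoint between native and denatured baselines)")
print(f"decay onset X0 = {fit.X0:.2f} degC, rate K = {fit.K:.4f} /degC")
print(f"native baseline {fit.native_baseline:.2f}, "
      f"denatured plateau {fit.denatured_plateau:.2f} (mean residue ellipticity)")
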