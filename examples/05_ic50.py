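"""Fit IC50 from a synthetic dose-response curve and predict inhibition.

Simulates triplicate-style measurements around a true IC50 of 30 uM with
5% multiplicative noise, fits the one-parameter model
vi/vo = 1/(1 + [I]/IC50), and uses the fit to predict single-dose
inhibition.
"""

from mmpscreen import fit_ic50, percent_inhibition, predict_velocity_ratio
from mmpscreen.fixtures import make_inhibition_curve

true_ic50 = 30.0  # uM
concentrations = [7.5, 15.0, 30.0, 60.0, 120.0]  # 20-80% inhibition
curve = make_inhibition_curve(true_ic50, concentrations, noise_sd=0.05,
                              seed=0)
for m in curve:
    print(f"  [I] = {m.concentration:6.1f} uM   vi/vo = "
          f"{m.velocity_ratio:.3f}   inhibition = "
          f"{m.inhibition_percent:5.1f}%")

fit = fit_ic50(curve)
print(f"\nfitted IC50 = {fit.ic50:.1f} +/- {fit.sd:.1f} uM "
      f"(true value {true_ic50:.0f} uM, {fit.n_points} points)")

inh100 = percent_inhibition(predict_velocity_ratio(fit.ic50, 100.0), 1.0)
print(f"predicted inhibition at 100 uM: {inh100:.1f}%")
# At [I] = IC50 the model gives exactly 50% inhibition; at higher doses
# inhibition approaches but never reaches 100%.
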