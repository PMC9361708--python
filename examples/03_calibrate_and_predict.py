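"""Noise-free parameter recovery: calibrate against the generated benchmark.

With all noise terms zero the generated channels are exactly consistent
with the forward model, so bounded least-squares calibration (inter-speed
mode: two steady cycles from each of five speeds) should recover the
generating parameters and predict held-out cycles almost perfectly.
"""

from hillfuse.benchmark import recovery_experiment
from hillfuse.synthetic import default_true_params

truth = default_true_params()
out = recovery_experiment(seed=1)

print("noise-free inter-speed calibration (seed 1):")
print(f"  objective at optimum : {out['objective']:.3e} (N*m)^2")
for m, label in (("lgs", "lateral gastrocnemius"), ("sol", "soleus")):
    tp = truth.muscle(m)
    print(f"  {label}:")
    print(f"    |delta error|      : {out[f'delta_err_{m}']:.2e}   (true delta {tp.delta})")
    print(f"    Fmax error         : {out[f'fmax_err_pct_{m}']:.2e} %  (true {tp.Fmax:.0f} N)")
print(f"  held-out R^2 (fit)   : {out['r2_fit']:.6f}")
print(f"  held-out N-RMSE (fit): {out['n_rmse_fit']:.2e} %")
print(
    "\nRecovery to numerical precision confirms the calibration pipeline is\n"
    "unbiased; real accuracy limits come from measurement noise, not the fit."
)
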