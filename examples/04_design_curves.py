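"""How many dilution steps and samples does a design need?

For each (dilution steps K, samples per group n) cell, simulate datasets
and summarise the plug-in (EC) and delta-method (ECVA1) standard errors of
the delta-delta-Cq estimate.  Longer dilution series pin down the
efficiencies and shrink the ECVA1 penalty toward zero; more samples shrink
both standard errors.  The median is reported alongside the mean because
the delta-method se has a heavy-tailed 1/gamma^2 component at small K.
"""

from ddcq import SimulationConfig, mean_se_curves

cfg = SimulationConfig(n_datasets=100, seed=5)
frame = mean_se_curves(cfg, K_values=(3, 6, 9), n_values=(4, 8),
                       hypotheses=("null",))

piv = frame.pivot_table(index=["n", "K"], columns="method", values="median_se")
piv["ECVA1/EC"] = piv["ECVA1"] / piv["EC"]
print(piv.round(3).to_string())
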