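"""Calibrate a simulated subject end to end and score held-out epochs.

Simulates a small oddball-paradigm subject (two electrodes carry a strong
P300, one carries none), runs the calibration wrapper — which banks
averaged-trial templates, scores each electrode by the AUROC of
template-to-trial chain distances, reduces the feature vector by stepwise
regression, and walks the stimulation count down — then validates the
returned profile on held-out trials. phi is the per-electrode mean AUROC
(0.5 = chance); psi is balanced classification accuracy.
"""

import numpy as np

from p300shape import CalibrationParams, SimulationConfig, calibrate, simulate_dataset, validate

cfg = SimulationConfig(
    n_electrodes=3,
    electrode_names=("Cz", "Pz", "Oz"),
    amplitude_profile=(1.0, 1.0, 0.0),
    p300_amplitude_uV=30.0,
    n_p300_train=40, n_nonp300_train=160,
    n_p300_valid=20, n_nonp300_valid=80,
    seed=21,
)
params = CalibrationParams(
    trials_per_template=12, max_stimulations=4,
    templates_per_electrode=2, max_folds=5, master_seed=21,
)

train, valid, truth = simulate_dataset(cfg)
profile = calibrate(train, params)

print("phi per electrode at each stimulation count k:")
print("  k  " + "  ".join(f"{n:>5s}" for n in cfg.electrode_names))
for k, phi in profile.phi_trace():
    print(f"  {k}  " + "  ".join(f"{v:5.3f}" for v in phi))
print(f"\nstatus: {profile.status}")
print(f"selected electrodes c': {profile.electrodes}")
print(f"optimum stimulations K': {profile.optimum_stimulations}")

report = validate(profile, valid, seed=0)  # averages K' trials per decision
print(f"\nvalidation on held-out epochs ({profile.optimum_stimulations}-trial averages):")
print(report.to_text())
print("Electrodes carrying the injected P300 rank on top, well above the 0.5")
print("chance line; averaging more stimulations per decision raises psi further.")
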