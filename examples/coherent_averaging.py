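"""Show how coherent averaging pulls the P300 out of background EEG.

Single trials bury a ~10 uV deflection in band-limited noise of similar
size; averaging K time-locked trials shrinks the noise by ~sqrt(K) while
the evoked bump survives. The correlation between the average and the
injected ground-truth bump quantifies the recovery.
"""

import numpy as np

from p300shape import SimulationConfig, coherent_average, simulate_dataset

cfg = SimulationConfig(seed=3, n_p300_train=180, n_nonp300_train=0,
                       n_p300_valid=0, n_nonp300_valid=0)
train, _, truth = simulate_dataset(cfg)
p300 = train.select_trials(train.label_indices("P300")).select_electrode("Fz")

print(" K    corr(average, true bump)")
for k in (1, 5, 15, 60, 180):
    avg = coherent_average(p300, indices=range(k))
    r = np.corrcoef(avg.y, truth["bump"])[0, 1]
    print(f"{k:4d}   {r:.3f}")
print("\nBy K=180 (the template-building count) the averaged waveform is")
print("nearly identical to the injected P300 shape.")
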