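"""Apparent Cm/Rm/Rs versus sine frequency on the synthetic cell.

Reproduces the baseline frequency-dependence study: a somatic voltage clamp
applies sine commands from 100 Hz to 10 kHz at three series resistances, and
the Sine+DC estimator reports apparent circuit parameters.  Electrotonic
attenuation makes the capacitance estimate fall steeply with frequency while
the three Rs curves coincide.
"""

import sinedc as sd
from sinedc import experiments as xp

cell = sd.generate_aii(sd.AiiGenParams())
passive = sd.TABLE1_PRESETS[13]
table = xp.run_baseline_sweep(cell, passive, xp.SweepConfig())

cm_theory = table["c_m_theory_pF"].iloc[0]
print(f"theoretical Cm = {cm_theory:.2f} pF, Rm = "
      f"{table['r_m_theory_GOhm'].iloc[0]:.3f} GΩ\n")
print(f"{'f (Hz)':>7} | " + " | ".join(f"Rs={rs:>3.0f} MΩ" for rs in (1.0, 50.0, 250.0))
      + " |  accuracy")
for f, grp in table.groupby("f_Hz"):
    cms = [grp[grp.rs_MOhm == rs]["c_m_pF"].iloc[0] for rs in (1.0, 50.0, 250.0)]
    acc = cms[1] / cm_theory
    print(f"{f:7.0f} | " + " | ".join(f"{c:9.2f}" for c in cms) + f" | {acc:9.2f}")

print("\nColumns are apparent Cm (pF): identical across Rs (noiseless clamp),")
print("near the 18.7 pF total at 100 Hz, and ~5× underestimated at 10 kHz.")
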