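"""Full time-domain pipeline: simulate, add noise, estimate per cycle.

Integrates the clamped cable equations for a 2 kHz sine command (1 µs steps),
adds pipette current noise, runs the per-cycle Sine+DC estimator on the
trace, applies the 10-cycle baseline averaging, and compares against the
frequency-domain oracle — the two independent routes must agree.
"""

import numpy as np

import sinedc as sd

cell = sd.generate_aii(sd.AiiGenParams())
passive = sd.TABLE1_PRESETS[13]
mesh = sd.discretize(cell, sd.DiscretizationSpec(0.01, 100.0), passive)
system = sd.assemble(mesh, passive,
                     sd.Electrode(rs=50.0, site=(0, cell.soma_id, 0.5)))

f, dt, settle, cycles = 2000.0, 1e-6, 20, 100
wave = sd.make_sine(sd.SineSpec(f_sine=f, amplitude=15.0, v_hold=-80.0),
                    (settle + cycles) / f, dt)
trace = sd.simulate(system, wave, dt)
noisy = sd.add_current_noise(trace, sd.NoiseSpec(current_sd=5.0, seed=7))

per_cycle = sd.estimate_trace(wave, noisy, f, v_hold=-80.0, settle_cycles=settle)
averaged = sd.average_baseline(per_cycle, sd.LockinConfig(baseline_lowpass=1e9))
oracle = sd.estimate_from_system(system, f, v_hold=-80.0, e_rev=-60.0)

print(f"sine 2 kHz ±15 mV, Rs 50 MΩ, {cycles} analyzed cycles, 5 pA noise")
print(f"per-cycle Cm:  {per_cycle['c_m_pF'].mean():.3f} pF "
      f"(sd {per_cycle['c_m_pF'].std()*1e3:.1f} fF)")
print(f"10-cycle avg:  {averaged['c_m_pF'].mean():.3f} pF "
      f"(sd {averaged['c_m_pF'].std()*1e3:.1f} fF)")
print(f"oracle:        {oracle.c_m:.3f} pF")
print(f"Rs estimate:   {per_cycle['r_s_MOhm'].mean():.2f} MΩ "
      "(true 50; overestimated on a branched cell at 2 kHz)")
print("\nBlock averaging shrinks the per-cycle noise ≈ √10-fold; the mean")
print("matches the frequency-domain oracle, validating the integrator.")
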