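"""Gap-junction coupling versus capacitance measurement.

Places 25 identical synthetic cells on a hexagonal 5×5 grid, couples nearest
neighbors through 20 gap-junction contacts per pair (sector rule, sorted by
depth), and measures the center cell.  Low sine frequencies "see" the coupled
neighbors — inflating the apparent Cm and destroying ΔCm detection — while
kilohertz sines are confined to the recorded cell.
"""

import sinedc as sd
from sinedc import experiments as xp

cell = sd.generate_aii(sd.AiiGenParams())
passive = sd.TABLE1_PRESETS[13]
lobulars = sorted(
    (s.id for s in cell.sections_with_label("lobular_appendage")),
    key=lambda i: sd.path_distance(cell, i, 0.5),
)
cfg = xp.SweepConfig(f_list=(100.0, 2000.0, 10000.0), rs_list=(50.0,),
                     gj_list=(0.0, 700.0, 3200.0, 5000.0))
table = xp.run_network_experiment(cell, passive, cfg, lobular_ids=[lobulars[8]])

theory = xp.delta_cm_theory_fF(0.5, passive.cm_spec)
base = table[table.kind == "baseline"]
delta = table[table.kind == "delta"]
print("pairwise Gj (pS) | Cm@100Hz | Cm@2kHz | Cm@10kHz | ΔCm@100Hz "
      f"(theory {theory:.2f} fF)")
for gj in cfg.gj_list:
    b = base[base.g_pair_pS == gj].set_index("f_Hz")["c_m_pF"]
    d = delta[(delta.g_pair_pS == gj) & (delta.f_Hz == 100.0)]["d_cm_fF"].iloc[0]
    print(f"{gj:16.0f} | {b[100.0]:8.2f} | {b[2000.0]:7.2f} | {b[10000.0]:8.2f}"
          f" | {d:8.2f} fF")

print("\nStrong coupling (≥3.2 nS) inflates the 100 Hz capacitance estimate by")
print("several pF and drives the 100 Hz ΔCm of a lobular surface increase to")
print("~0 or negative, while the ≥2 kHz columns barely move: high-frequency")
print("measurements are protected from coupling but blind to distal sites.")
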