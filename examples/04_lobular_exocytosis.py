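"""Detecting a localized surface-area increase (simulated exocytosis).

Adds 0.5 µm² of membrane to single lobular appendages at different path
distances from the soma — mimicking the fusion of ~100 synaptic vesicles —
and measures the resulting apparent capacitance change ΔCm with a somatic
electrode.  Accuracy = ΔCm(measured)/ΔCm(implemented): high at 100 Hz for
every site, strongly distance-dependent in the kHz range.
"""

import sinedc as sd
from sinedc import experiments as xp

cell = sd.generate_aii(sd.AiiGenParams())
passive = sd.TABLE1_PRESETS[13]
lobulars = sorted(
    (s.id for s in cell.sections_with_label("lobular_appendage")),
    key=lambda i: sd.path_distance(cell, i, 0.5),
)
sites = [lobulars[0], lobulars[8], lobulars[-1]]
cfg = xp.SweepConfig(f_list=(100.0, 1000.0, 2000.0, 10000.0), rs_list=(50.0,))
table = xp.run_lobular_delta(cell, passive, sites, (0.5,), cfg)

theory = xp.delta_cm_theory_fF(0.5, passive.cm_spec)
print(f"implemented ΔCm = 0.5 µm² × {passive.cm_spec} µF/cm² = {theory:.2f} fF\n")
print(f"{'site':>5} {'distance':>9} | " + " | ".join(
    f"{f/1000:g} kHz" for f in cfg.f_list))
for sec in sites:
    grp = table[table.section == sec]
    d = grp["distance_um"].iloc[0]
    accs = [grp[grp.f_Hz == f]["accuracy"].iloc[0] for f in cfg.f_list]
    print(f"{sec:5d} {d:7.1f} µm | " + " | ".join(f"{a:7.2f}" for a in accs))

print("\nEach entry is the detection accuracy ΔCm/ΔCm(theory).  At 100 Hz all")
print("sites are detected nearly in full; at 2 kHz the distal appendage's")
print("signal is mostly lost to electrotonic attenuation.")
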