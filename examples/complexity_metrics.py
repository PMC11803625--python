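"""Compare information metrics across the three protocell system analogs.

Generates pristine (P), serotonin (PS) and serotonin-paroxetine (PSP)
trace analogs and computes LZW complexity, PCI, integration score and
integrated information Phi for each.
"""

from protoneuro import SYSTEM_PRESETS, consciousness_report, gen_spike_trace

print(f"{'system':>6} {'C_LZW':>8} {'PCI':>8} {'I':>8} {'Phi (bits)':>11}")
reports = {}
for name, phases in SYSTEM_PRESETS.items():
    trace = gen_spike_trace(phases(30_000.0), dt=1.0, seed=11, label=name)
    rep = consciousness_report(trace, n_windows=10, bins=16)
    reports[name] = rep
    print(f"{name:>6} {rep.c_lzw:8.4f} {rep.pci:8.4f} "
          f"{rep.integration:8.3f} {rep.phi:11.3f}")

print()
print("The serotonin system (PS) is the most LZW-complex and the most")
print("integrated; the pristine system (P) is the least complex, with the")
print("serotonin-paroxetine system (PSP) in between - the same hierarchy")
print("reported for the recorded protocells.")
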