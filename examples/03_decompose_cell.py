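"""Optogenetic decomposition of one simulated voltage-clamp cell.

Simulates a noiseless adult-preset cell (total EPSCs with LED off,
thalamic EPSCs with cortical silencing LED on), runs the per-cell
pipeline, and compares every recovered quantity with generator truth.
"""

from binomatch import (GeneratorConfig, StimulusProtocol, assemble_cell,
                       generate_cell)

cfg = GeneratorConfig.preset("adult", n_cells=1, seed=8, noise_sd=0.0)
protocol = StimulusProtocol()
sweeps, truth = generate_cell(cfg, protocol, 0)
result = assemble_cell(sweeps, protocol)

print(f"cell {result.cell_id}: {len(sweeps)} sweeps "
      f"(2 eyes x 2 LED states x 12 directions x {cfg.n_trials} trials "
      f"+ blanks)")
for eye in ("contra", "ipsi"):
    print(f"\n{eye} eye:")
    for itype in ("total", "thalamic", "cortical"):
        st = result.stats[(eye, itype)]
        print(f"  {itype:9s} pref_O = {st.pref_o:+7.2f} deg, "
              f"gOSI = {st.gosi:.3f}")
    print(f"  truth: thalamic {truth.pref_thalamic[eye]:+7.2f}, "
          f"cortical {truth.pref_cortical[eye]:+7.2f} deg")
    print(f"  scale factor = {result.scale_factor[eye]:.3f} "
          f"(truth {truth.scale_factor[eye]:.2f})")
print(f"\ndelta O (inter-ocular): total {result.delta_o['total']:.1f}, "
      f"thalamic {result.delta_o['thalamic']:.1f}, "
      f"cortical {result.delta_o['cortical']:.1f} deg")
print(f"contra/ipsi amplitude ratio: total "
      f"{result.ci_ratio_total:.2f}, thalamic "
      f"{result.ci_ratio_thalamic:.2f} (truth {cfg.ci_ratio})")
print()
print("The cortical EPSC is obtained by point-by-point subtraction of")
print("the LED-on (thalamic) from the LED-off (total) cycle-averaged")
print("trace; with zero noise every preference and the thalamic/total")
print("scale factor are recovered essentially exactly.")
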