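"""Repeated double cross-validation with stability-based band selection.

Runs the full engine (reduced to 5 runs for a quick demonstration) on the
four-class population: inner-loop model selection with CovSel, outer-loop
validation, per-wavelength selection frequencies, the stable subset
(selected in >= 80% of outer models) and its confirmation run.
"""

import numpy as np

import berryvis as bv
from berryvis.rdcv import RDCVConfig, rdcv_on_subset, run_rdcv, selection_frequency, stable_subset

data = bv.generate_spectra(bv.SimulationConfig(seed=1))
config = RDCVConfig(
    n_runs=5, n_outer=10, n_inner=9, seed=42,
    selection="covsel", lv_grid=(1, 2, 3, 4, 5, 6),
    n_select_grid=(10, 20, 30, 40),
)
res = run_rdcv(data, config)
agg = res.aggregated
print(f"{res.n_models} outer models ({config.n_runs} runs x {config.n_outer} splits)")
print(f"four-class accuracy: {agg.mean.accuracy:.1f} +/- {agg.std.accuracy:.1f} %")
print(f"mean class error:    {agg.mean.error:.1f} +/- {agg.std.error:.1f} %")

freq = selection_frequency(res)
subset = stable_subset(freq, res.grid, config.stability_threshold)
print(f"\nstable subset: {subset.size} wavelengths selected in >=80% of models")
print("  " + "  ".join(f"{w:.0f}" for w in subset))

confirmed = rdcv_on_subset(data, subset, config)
print(f"\nconfirmation rDCV on the stable subset alone: "
      f"accuracy {confirmed.aggregated.mean.accuracy:.1f} +/- "
      f"{confirmed.aggregated.std.accuracy:.1f} %")
print("\nA compact, stable set of wavelengths carrying the class "
      "information supports the same (or better) external-validation "
      "performance as the full spectrum -- the basis for a cheap "
      "multispectral sorting implementation.")
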