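"""Simulate a crossover dataset and summarize it.

Draws transmitted chromatids for 100 meioses per sex across the 19 mouse
autosomes under the gamma-sprinkling interference model, then prints the
descriptive statistics. Because the observed crossover process has rate 1
per Morgan, the per-meiosis means track the sex-specific map totals
(13.55 F / 12.21 M expected at the full map), and strong interference
pushes the inter-crossover distances far above the ~33 cM a Poisson
process would give on these chromosomes.
"""

import gammaxo as gx

spec = gx.SimSpec(n_meioses_per_sex=100, seed=1)
data = gx.simulate_dataset(spec)

print(f"simulated {len(data.records)} transmitted chromosomes "
      f"({data.n_crossovers} crossovers)\n")
print(gx.compute_descriptives(data))
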