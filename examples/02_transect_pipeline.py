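"""Transect pipeline: synthetic cruise -> per-cell growth rates -> summaries.

Generates a subtropical-to-subantarctic transect, draws imaged cells along
it, applies the diffusion model to each with locally interpolated nutrients,
and summarizes which cells are diffusion-limited and what alternative N
strategies they carry.
"""
import numpy as np

from osmolimit import (
    CruiseScenario,
    apply_model,
    bin_and_summarize,
    default_taxon_profiles,
    limited_cell_strategy_summary,
    simulate_cells,
    simulate_cruise,
)
from osmolimit.track import Region

stations, underway = simulate_cruise(CruiseScenario(seed=1))
cells = simulate_cells(default_taxon_profiles(), 1500, stations, underway, seed=2)
results, dropped = apply_model(cells, stations, underway)
print(f"{len(results)} cells modelled ({dropped} dropped)")

for region in Region:
    rs = [r for r in results if r.region is region]
    if not rs:
        continue
    limited = sum(r.gr_n < 0.2 for r in rs)
    print(f"{region.value:12s}: {len(rs):4d} cells, "
          f"{100 * limited / len(rs):5.1f}% below 0.2/d, "
          f"median GR_N {np.median([r.gr_n for r in rs]):8.2f}/d")

summary = limited_cell_strategy_summary(results, threshold=0.2)
print(f"\nsubtropical cells below 0.2/d: {summary['n_limited']}")
print(f"  with alternative N strategy (diazotrophy/mixotrophy/DDA): "
      f"{summary['alternative_strategy_percent']:.0f}%")

table = bin_and_summarize(results)
print("\nfunctional-group proportions per region x growth bin (head):")
print(table.head(8).to_string(index=False))
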