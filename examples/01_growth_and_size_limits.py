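"""Single-cell worked example: quotas, diffusive uptake, growth rates, size limits.

A 10-um spherical cell in warm oligotrophic water (ammonium 100 nmol/L as
the only N source, phosphate 100 nmol/L, diffusivities forced to 1e-5
cm^2/s so every number can be checked by hand).
"""
from osmolimit import (
    CellGeometry,
    NutrientField,
    SeawaterState,
    cell_quota,
    critical_esd,
    n_based_max_growth,
    p_based_max_growth,
)

state = SeawaterState(temperature=20.0, salinity=35.0)
field = NutrientField(ammonium=100.0, nitrite=0.0, nitrate=0.0, phosphate=100.0)
cell = CellGeometry(esd=10.0)

quota = cell_quota(cell.biovolume)
print(f"biovolume           : {cell.biovolume:9.2f} um^3")
print(f"N quota             : {quota.n_content:.4e} nmol N/cell")
print(f"P quota (N/16)      : {quota.p_content:.4e} nmol P/cell")

gr_n = n_based_max_growth(cell, field, state, diffusivity_override=1e-5)
gr_p = p_based_max_growth(cell, field, state, diffusivity_override=1e-5)
print(f"max N-based growth  : {gr_n:.4f} /d   (diffusion-limited ceiling)")
print(f"max P-based growth  : {gr_p:.4f} /d   (P never binds before N here)")

limit = critical_esd(0.2, field, state, diffusivity_override=1e-5)
print(f"size limit at 0.2/d : {limit:.2f} um  (larger cells cannot reach 0.2/d)")

with_urea = NutrientField(ammonium=100.0, nitrite=0.0, nitrate=0.0,
                          phosphate=100.0, urea=200.0)
limit_urea = critical_esd(0.2, with_urea, state, diffusivity_override=1e-5)
print(f"... adding 200 nmol/L urea raises it to {limit_urea:.2f} um")
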