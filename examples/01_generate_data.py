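"""Generate the three synthetic inputs: trials, a region, a PNEC inventory.

The trial table emulates a literature-compiled wetland-antibiotics data set
(16 numeric + 3 categorical features, removal efficiency in percent as the
target, 10% of numeric cells missing at random).  The region holds counties
with heavy-tailed annual antibiotic emissions and wetland inventories; the
inventory's minimum PNEC (3 ng/L) drives the cask-effect risk quotient.
"""

from wetrisk import synthgen

trials = synthgen.gen_experiments(n=337, seed=1, missing_rate=0.1)
print(f"trials: {trials.shape[0]} rows x {trials.shape[1]} columns")
print(f"  target range: {trials['are'].min():.1f}-{trials['are'].max():.1f} % removal")
numeric = [c for c in trials.columns if trials[c].dtype.kind == "f" and c != "are"]
missing = trials[numeric].isna().to_numpy().mean()
print(f"  missing cells: {missing:.1%} of the numeric feature block")

region, inventory = synthgen.gen_region(n_counties=60, seed=1, n_antibiotics=80)
print(f"region: {len(region.counties)} counties, {len(region.wetlands)} wetlands, "
      f"{region.total_wetland_area:.0f} km2 of wetland")
print(f"  annual emissions: {region.total_emission:.0f} t across the region")
print(f"inventory: {inventory.n} antibiotics, minimum PNEC "
      f"{inventory.min_pnec:.0f} ng/L (the most sensitive compound sets the risk scale)")
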