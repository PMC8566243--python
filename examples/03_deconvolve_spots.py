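"""Deconvolve multi-cell spots into individually typed segmented cells.

Maps more single-cell profiles than there are segmented cells in a spot
region; the learned filter selects which profiles are placed, the count term
matches the segmented total, and each placed profile is assigned to a
segmented cell within its most probable spot.
"""

import numpy as np

import voxmap as vm

truth = vm.standard_suite(seed=0)
sc_n = vm.log1p_transform(vm.normalize_library_size(truth.sc))
panel = vm.training_panel(vm.rank_markers(sc_n), k=10, sp=truth.sp)

# restrict the spatial side to half the tissue so profiles outnumber segments
n_sub = 50
sp_sub = vm.SpatialMatrix(truth.sp.values[:n_sub], truth.sp.voxel_ids[:n_sub],
                          truth.sp.gene_ids)
seg = truth.seg_counts[:n_sub]
print(f"{truth.sc.n_cells} profiles available, {seg.sum()} segmented cells "
      f"in the {n_sub}-spot region")

sc_t, sp_t = vm.intersect_genes(truth.sc, sp_sub, panel=panel)
config = vm.mode_deconvolution(sc_t, sp_t, seg)
density = config.pop("density")
result = vm.fit(sc_t, sp_t, density, epochs=3000, seed=0, **config)

n_filtered = int((result.f > 0.5).sum())
print(f"cells passing the filter (f > 0.5): {n_filtered} "
      f"({n_filtered / seg.sum():.0%} of segmented cells)")

assignment = vm.deconvolve(result, truth.sc.labels, seg, seed=0)
placed = assignment.table[assignment.table["sc_cell_id"] != ""]
print(f"segmented cells receiving a typed profile: {len(placed)} / {seg.sum()}")
print(placed.head(6).to_string(index=False))
print("(each row places one single-cell profile, with its type, onto one"
      " segmented cell of one spot)")
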