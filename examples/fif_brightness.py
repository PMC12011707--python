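"""Receptor oligomerization from fluorescence intensity fluctuations.

Simulates photon-counting membrane images for three receptor populations —
pure monomer (the LAT-like control), pure dimer, and a 50/50 mixture —
segments each cell's ROI into 15x15-pixel tiles, computes the molecular
brightness epsilon = (1/gamma)(variance/mean - 1) per segment, and compares
the pooled distributions.
"""

from stabkit import fif, synthetic

N_CELLS = 100
populations = {
    "monomer": {1: 1.0},
    "dimer": {2: 1.0},
    "ligand-bound (50/50 mix)": {1: 0.5, 2: 0.5},
}

dists = {}
for i, (name, mix) in enumerate(populations.items()):
    cells = []
    for c in range(N_CELLS):
        img, mask, _ = synthetic.gen_membrane_image(
            shape=(60, 60), oligomer_mix=mix, seed=1000 * i + c
        )
        stats = fif.tile_roi(img, mask)  # 15x15 tiles fully inside the ROI
        cells.append(fif.segment_brightness(stats, gamma=0.5))
    dists[name] = fif.aggregate_distribution(cells, min_cells=100)
    expected = synthetic.expected_brightness(mix)
    print(f"{name}: mean brightness {dists[name].mean:6.2f} "
          f"(closed-form expectation {expected:.2f}; "
          f"{dists[name].n_segments} segments from {dists[name].n_cells} cells)")

mono = dists["monomer"]
dimer = dists["dimer"]
mix = dists["ligand-bound (50/50 mix)"]
cmp_ = fif.compare_to_control(mix, mono, dimer)
print(f"dimer/monomer mean-brightness ratio: {dimer.mean / mono.mean:.2f} "
      "(brightness is proportional to oligomer size)")
print(f"mixture position on the monomer->dimer axis: {cmp_.position:.2f} "
      f"-> classified {cmp_.classification}")
# A population whose spectrum sits strictly between the controls indicates
# coexisting ligand-bound monomers and dimers.
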