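"""Convert single-nucleotide occupancy into an expected ChIP-seq profile.

Start-position occupancy is expanded over the protein footprint and
smoothed with a fragment-length kernel, mimicking the enrichment shape a
ChIP experiment would report around a bound site.
"""

import numpy as np

import tfocc

# a strong operator (~8 kBT) so the peak stands out over background
substrate = tfocc.make_substrate(seed=24, dna_length=4000, top_site_energy=8.0)
design = tfocc.StudyDesign(dna_length=4000)
config = design.cell_config(substrate, n_cognate=2, coverage=0.0,
                            t_end=2e5, seed=3)
records = tfocc.simulate_replicates(config, 4, base_seed=9)
sdo = tfocc.sdo_hybrid(records, tfocc.COGNATE)

profile = tfocc.smooth_profile(sdo, tfocc.ProfileConfig(fragment_length=100),
                               footprint=substrate.motif.length)
peak = int(np.argmax(profile))
enrichment = profile.max() / np.median(profile)
print(f"profile peak at bp {peak} (planted site at "
      f"{substrate.manifest.loc[0, 'position']})")
print(f"enrichment over median background: {enrichment:.1f}-fold")
tfocc.write_wig(profile, "scratch/profile.wig", chrom="synthetic")
print("wrote scratch/profile.wig")
# the single-bp occupancy spike becomes a fragment-sized enrichment peak
# centered on the planted site -- the resolution a read-level assay sees.
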