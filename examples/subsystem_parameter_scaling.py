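"""Adapt full-genome parameters to a small simulated DNA segment.

Highly abundant species keep their association rate and scale their copy
number with the length ratio; low-copy species keep their copy number
and recalibrate the association rate so the fraction of time spent on
the DNA matches the full-system value.
"""

import numpy as np

import tfocc
from tfocc.scaling import calibration_report_tsv

# copy-number model: 10,000 crowders on a 4.6 Mb genome -> 10 kb segment
n_sub = tfocc.copy_number_scale(10_000, l_sub=10_000, l_full=4_600_000)
print(f"copy-number model: 10000 molecules -> {n_sub} in the 10 kb subsystem")

# association-rate model: calibrate k so a lone TF is DNA-bound 75% of time
lsc = tfocc.flat_landscape(200, tau0=1.0, footprint=1)
sp = tfocc.SpeciesParams(name="tf", footprint=1, abundance=1, k_assoc=0.5,
                         landscape=lsc, move_probs=(0.0, 0.0, 0.0, 1.0))
config = tfocc.SimConfig(dna_length=200, species=[sp], t_end=3000.0, seed=1)
report = []
k = tfocc.calibrate_association_rate(0.75, config, tol=0.02, n_eval=6,
                                     seed=5, report=report)
print(f"association-rate model: k_assoc = {k:.2f} per second "
      f"(two-state theory: {0.75/0.25:.2f})")
calibration_report_tsv(report, "scratch/calibration.tsv")
print(f"{len(report)} calibration iterations -> scratch/calibration.tsv")
# the calibrated rate matches the closed-form two-state answer k = u f/(1-f).
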