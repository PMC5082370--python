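"""Simulate single-cell clock trajectories and find their principal period.

Runs the default bursting transcription-translation clock for 64 isolated
cells over 10 days with the exact Gillespie algorithm, detrends the CCG-2
recorder signal with a 24-h moving average, and averages the per-cell
normalized periodograms.
"""

import numpy as np

from dropclock.gillespie import (
    build_default_clock,
    ensemble_species_matrix,
    gillespie_ensemble,
)
from dropclock.preprocess import moving_average_detrend
from dropclock.spectral import average_periodogram, periodogram_set
from dropclock.tables import TrajectorySet

net = build_default_clock()
print(f"network: {len(net.species)} species, {len(net.reactions)} reactions")

trajs = gillespie_ensemble(net, n_cells=64, t_end=240.0, frame_dt=0.5, seed=1)
ccg2 = ensemble_species_matrix(trajs, "CCG2").astype(float)
mrna = ensemble_species_matrix(trajs, "ccg2_mrna")
print(f"mean ccg-2 mRNA {mrna.mean():.0f} molecules/cell, "
      f"CCG-2 protein {ccg2.mean():.0f} molecules/cell")

ts = TrajectorySet(
    values=ccg2,
    cell_ids=[f"c{i}" for i in range(64)],
    droplet_ids=[f"d{i}" for i in range(64)],
)
avg = average_periodogram(periodogram_set(moving_average_detrend(ts)))
peak = 1.0 / avg.freqs[int(np.argmax(avg.mean))]
print(f"principal period of the cell-averaged periodogram: {peak:.1f} h")
# Each cell oscillates with a ~21 h circadian period, but phases and
# amplitudes disperse across cells because transcription is bursty and
# molecule counts are low; the averaged periodogram still peaks sharply.
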