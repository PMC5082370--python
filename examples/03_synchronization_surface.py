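"""Measure cell-to-cell synchronization with the ICC surface.

Couples cells within droplets (Kuramoto phase dynamics), computes the
intraclass-correlation surface over (droplet size, time), and destroys the
signal with the strangers-resampling control.
"""

import numpy as np

from dropclock.quorum import KuramotoParams, kuramoto_signal_matrix
from dropclock.synchrony import icc_surface, strangers_control
from dropclock.synth import DropletLayout
from dropclock.tables import TrajectorySet

sizes = [1] * 60 + [2] * 60 + [4] * 30
layout = DropletLayout(
    droplet_ids=[f"d{i}" for i in range(len(sizes))],
    cells_per_droplet=np.array(sizes),
)
sig = kuramoto_signal_matrix(layout, KuramotoParams(K_c=0.12), 240.0, seed=7)
dids, cids = layout.cell_assignments()
ts = TrajectorySet(values=sig, cell_ids=cids, droplet_ids=dids)

surface = icc_surface(ts)
for i, a in enumerate(surface.a_levels):
    v = surface.values[i]
    print(f"a={a}: mean ICC first 60 h {np.nanmean(v[:120]):.2f} -> "
          f"last 60 h {np.nanmean(v[-120:]):.2f} ({surface.n_droplets[i]} droplets)")

nulls = strangers_control(ts, n_reps=5, seed=3)
null_abs = np.mean([np.nanmean(np.abs(s.values)) for s in nulls])
print(f"strangers control mean |ICC|: {null_abs:.3f}")
# A rising ICC along the time axis means neighbors within a droplet grow
# more similar than cells in different droplets — evidence of
# communication; replacing neighbors with random singletons flattens the
# surface to noise around zero.
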