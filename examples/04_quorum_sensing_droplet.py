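"""Quorum-sensing droplet model: a shared signal synchronizes clocks.

Each cell runs the deterministic clock; a CCG-2-driven signaling molecule
exchanges with the droplet medium and represses WCC formation in every
cell, closing a population-level negative feedback loop.
"""

import numpy as np

from dropclock.quorum import QuorumParams, model_icc_surface, simulate_droplet

params = QuorumParams()  # eta=100, eta_ext=1.44, D9=26, D10=4, C4=0.8, ...
tr = simulate_droplet(params, t_end=240.0, a=4)
ccg = tr.ccg
print(f"within-droplet CCG-2 dispersion: first 48 h "
      f"{ccg[:, :96].std(axis=0).mean():.1f} -> last 48 h "
      f"{ccg[:, -96:].std(axis=0).mean():.1f} (molecule-equivalent units)")

surf = model_icc_surface([2, 4], n_droplets=4, params=params, t_end=240.0, seed=5)
for i, a in enumerate(surf.a_levels):
    v = surf.values[i]
    print(f"model ICC surface a={a}: {np.nanmean(v[:120]):.2f} -> "
          f"{np.nanmean(v[-120:]):.2f}")
# Cells started at dispersed phases converge: the model predicts the same
# rising synchronization surface the droplet measurements show.
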