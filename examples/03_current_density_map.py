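"""Omnidirectional current-density mapping on a resistance raster.

Random source/ground pairs are placed on a conductive buffer outside the
study-area perimeter (avoiding node placement bias), per-pair current
densities are averaged, and the map is standardized to mean zero.  A
pinch point — a low-cost corridor through resistant land — stands out as
high current.
"""

import numpy as np

from landconnect import Raster, omnidirectional_map, write_ascii_grid

# two resistant blocks joined by a single-cell corridor
data = np.full((25, 25), 1000.0)
data[12, :] = 10.0
raster = Raster(data, cell_size=100.0)

cmap = omnidirectional_map(raster, n_pairs=64, buffer_cells=6, seed=3)
vals = cmap.current.data[np.isfinite(cmap.current.data)]
corridor = cmap.current.data[12, 12]
print(f"map standardized mean: {np.nanmean(cmap.current.data):+.2e} "
      f"(zero by construction); raw mean before standardizing: {cmap.raw_mean:.4f}")
print(f"corridor cell density {corridor:+.3f} vs 95th percentile "
      f"{np.percentile(vals, 95):+.3f}")
write_ascii_grid(cmap.current, "current_density.asc")
print("wrote current_density.asc")
print("-> the corridor concentrates nearly all cross-block current: a")
print("   geometric pinch point with high movement probability.")
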