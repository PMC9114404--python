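"""Slope, aspect and bathymetric position index from a bathymetry grid.

BPI compares each cell with the mean of a surrounding disc: positive on
seamounts and hills, negative in troughs and moats.  The two radii (1 km
and 17 km) separate fine ridge texture from broad seamount relief.
"""

import numpy as np

from benthoscape import seascape as sc
from benthoscape.terrain import terrain_stack

spec = sc.SeascapeSpec(nrows=100, ncols=160, seed=0)
depth = sc.generate_bathymetry(spec)
stack = terrain_stack(depth, bpi_radii_m=(1000.0, 17000.0))

for name in stack.names:
    vals = stack[name].values
    vals = vals[np.isfinite(vals)]
    print(f"{name:>12}: min {vals.min():9.2f}  mean {vals.mean():9.2f}  "
          f"max {vals.max():9.2f}")

summit = np.unravel_index(np.nanargmin(depth.values), depth.values.shape)
print(f"\nat the shallowest cell {summit}: "
      f"depth {depth.values[summit]:.0f} m, "
      f"broad-scale BPI {stack['bpi_17000'].values[summit]:+.0f} m "
      "(strongly positive = locally elevated, as a summit should be)")
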