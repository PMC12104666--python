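"""Local breeding density from truncated Thiessen (Voronoi) polygons.

Each active nest gets the region of the plane closer to it than to any
other nest, truncated at 12.7 km (the population's historical mean
nearest-neighbour distance); local density is the reciprocal polygon
area in 1/km^2. An isolated nest gets the full disc, crowded nests get
small cells.
"""

import math

import numpy as np
import pandas as pd

from natdisp.density import DEFAULT_R_TRUNC_KM, truncated_thiessen
from natdisp.geo import LocalEqualAreaProjection

proj = LocalEqualAreaProjection(19.5, 47.2)

# one isolated nest, plus a cluster of five nests ~6 km apart
xy = np.array([[60.0, 60.0],
               [0.0, 0.0], [6.0, 0.0], [0.0, 6.0], [6.0, 6.0], [3.0, 3.0]])
lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
nests = pd.DataFrame({"territory_id": ["isolated", "c1", "c2", "c3", "c4",
                                       "centre"],
                      "year": 2020, "lon": lon, "lat": lat})

cells = truncated_thiessen(nests, projection=proj)
print(f"truncation disc area: pi * {DEFAULT_R_TRUNC_KM}^2 = "
      f"{math.pi * DEFAULT_R_TRUNC_KM**2:.2f} km^2\n")
for cell in cells:
    print(f"{cell.territory_id:>8}: area {cell.area:7.2f} km^2, "
          f"density {cell.density:.5f} /km^2, truncated={cell.truncated}")
print("\nthe isolated nest's density is the floor 1/(pi r^2) ~ 0.00197; "
      "the central nest of the cluster is ~25x denser.")
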