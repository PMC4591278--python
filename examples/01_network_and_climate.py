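"""Build a synthetic basin chain with its seasonal climate.

Generates a 20-basin latitudinal chain emulating an Atlantic-style coast,
attaches a stationary seasonal water-temperature series, and prints the
latitudinal temperature gradient and the inter-basin distance scale.
"""

import numpy as np

import diadrom as dd

network = dd.make_network(n_basins=20, seed=1)
climate = dd.make_climate(network, years=30, seed=1)

south, north = network.basins[0], network.basins[-1]
print(f"{len(network)} basins from {south.outlet_lat:.1f}N to {north.outlet_lat:.1f}N")
print(f"surface areas: median {np.median(network.surface_areas):,.0f} km2, "
      f"max {network.surface_areas.max():,.0f} km2")
print(f"neighbour spacing ~{network.distances[0, 1]:.0f} km")

for bid in (south.id, north.id):
    summer = climate.reference_mean(bid, "summer")
    winter = climate.reference_mean(bid, "winter")
    print(f"basin {bid}: summer {summer:.1f} C, winter {winter:.1f} C (water)")
# The summer-winter spread is the seasonal amplitude; the south-north summer
# difference is the latitudinal lapse times the latitude span.
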