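"""Derived environmental descriptors: shoreline development, land-cover
diversity, and maximum between-pond distance.

Shoreline development DL = L / (2 sqrt(pi A)) compares a pond's perimeter to
the circumference of the equal-area circle: 1 for a circular pond, larger
for convoluted shorelines (more littoral habitat per unit area). Land-cover
diversity is the Shannon entropy of cover fractions in a buffer around the
pond. Maximum pairwise distance (great-circle, km) describes the spatial
extent of a pond network.
"""

import numpy as np

import metapart as mp

ponds = {
    "circular pond (r=25 m)": (2 * np.pi * 25, np.pi * 25**2),
    "square pond (50 m side)": (200.0, 2500.0),
    "dendritic wetland": (900.0, 8000.0),
}
print("shoreline development index:")
for name, (perimeter, area) in ponds.items():
    dl = mp.shoreline_development(perimeter, area)
    print(f"  {name:26s} DL = {dl:.3f}")

print()
covers = {
    "monoculture buffer": [1.0, 0, 0, 0],
    "two equal covers": [0.5, 0.5, 0, 0],
    "mixed mosaic": [0.4, 0.3, 0.2, 0.1],
}
print("land-cover Shannon diversity:")
for name, fractions in covers.items():
    print(f"  {name:26s} H = {mp.landcover_shannon(fractions):.3f}")

print()
rng = np.random.default_rng(2)
# a pond network spanning roughly 2 degrees of longitude at mid-latitude
coords = np.column_stack([rng.uniform(-1.0, 1.0, 30), rng.uniform(39.0, 40.5, 30)])
print(f"maximum between-pond distance: {mp.max_pairwise_distance_km(coords):.1f} km")
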