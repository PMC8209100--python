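"""Build the synthetic toy world and look at what it contains.

The world is a grid street network with pedestrian-eligible classes and
a few motorways, square parks, categorized POIs on walkable streets,
and census tracts tiling the extent (assigned round-robin to
metropolitan areas).  Everything is deterministic given the seed.
"""

import walkpulse as wp

cfg = wp.WorldConfig(seed=7)
world, tract_skeleton = wp.build_world(cfg)

print(f"pedestrian segments : {len(world.pedestrian)}")
print(f"excluded (motorway) : {len(world.excluded)}")
print(f"parks               : {len(world.parks)}")
print(f"POIs                : {len(world.pois)}")
print(f"tracts / MSAs       : {len(world.tracts)} / "
      f"{world.tracts['msa_id'].nunique()}")
print("\nPOI category mix (drawn from the configured weights):")
print(world.pois["category"].value_counts().to_string())

# The counts above describe the stage on which traces are simulated:
# walks are routed on the pedestrian grid, drives on the motorways,
# and trip destinations are POIs -- so detection and classification
# can be scored against known ground truth.
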