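"""Generate a synthetic fluorescent seed plate and segment it.

A plate is a petri dish of Camelina seeds; under fluorescent imaging the
seeds glow in the red channel on a dark background.  Segmentation
thresholds the red channel and labels each seed by contour tracing.
"""

from seedsalt import count_objects, generate_plate, preset, segment
from seedsalt.synthetic import default_spec

spec = default_spec("FLUO", "non-salt", seed=7, n_seeds=60)
plate = generate_plate(spec)
config = preset("FLUO")

regions = segment(plate.image, config)
print(f"generated {len(plate.truth)} seeds, detected {len(regions)} regions")
print(f"count_objects: {count_objects(plate.image, config)}")

largest = max(regions, key=lambda r: r.area)
print(f"largest region: label {largest.label}, area {largest.area} px, "
      f"contour of {len(largest.outer_contour)} boundary pixels")

# The detected count should equal the generated count: non-overlapping
# seeds are well separated from the dark background in the red channel.
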