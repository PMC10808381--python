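"""Classify plate salt status by 13-classifier consensus.

Seeds from salt-grown plants are larger and fluoresce more strongly in
the red channel.  One labeled training plate per condition is enough:
each of the 13 classifiers labels every test seed, the percentage of
salt-labeled seeds per algorithm is averaged, and the plate is called
salt when that consensus exceeds 50.
"""

from seedsalt import (classify_plates, extract_plate_table, generate_dataset,
                      preset, train_ensemble)
from seedsalt.synthetic import default_spec

config = preset("FLUO")
salt = default_spec("FLUO", "salt")          # +30% size, +40 red intensity
non = default_spec("FLUO", "non-salt")

def labeled_records(plates):
    records = []
    for plate in plates:
        records.extend(extract_plate_table(plate.image, config,
                                           condition=plate.condition))
    return records

train = generate_dataset(1, salt, non, seed=1)   # 1 plate per condition
test = generate_dataset(3, salt, non, seed=2)    # 6 test plates

model = train_ensemble(labeled_records(train), subset="all", seed=17)
predictions = classify_plates(model, labeled_records(test))

truth = {p.image.id: p.condition for p in test}
correct = 0
for pred in predictions:
    ok = pred.status == truth[pred.plate]
    correct += ok
    print(f"{pred.plate}: consensus {pred.consensus:5.1f} -> {pred.status:9s} "
          f"(truth {truth[pred.plate]}, {'ok' if ok else 'WRONG'})")
print(f"plate accuracy: {correct}/{len(predictions)}")

# Consensus near 100 or 0 means the algorithms agree on nearly every seed;
# values near 50 flag ambiguous plates.
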