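"""Extract the per-seed morpho-colorimetric trait table and summarize it.

Each seed yields 7 shape features and 16 color features; with a px/cm
scale (here from the dish geometry: 8.5 cm inner diameter) the mean seed
length and width are reported in millimeters.
"""

from seedsalt import (ScaleCalibration, extract_plate_table, generate_plate,
                      plate_summary, preset, write_feature_csv)
from seedsalt.synthetic import default_spec

plate = generate_plate(default_spec("FLUO", "non-salt", seed=11))
records = extract_plate_table(plate.image, preset("FLUO"))
write_feature_csv(records, "plate_features.csv")
print(f"wrote {len(records)} seed records to plate_features.csv")

cal = ScaleCalibration(px_per_cm=plate.image.px_per_cm, source="dish inner diameter")
summary = plate_summary(records, cal)
print(f"seeds: {summary.n_seeds}")
print(f"mean area: {summary.mean_area_px:.1f} px ({summary.mean_area_mm2:.3f} mm^2)")
print(f"mean length x width: {summary.mean_length_mm:.2f} x {summary.mean_width_mm:.2f} mm")
print(f"mean circularity: {summary.mean_circularity:.2f}")

# Length ~2 mm and width ~1 mm match real Camelina seeds; circularity is
# above the 4*pi ~ 12.57 of a perfect disc because seeds are elongated.
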