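"""Count nuclei and measure collagen area on a trichrome-like image.

A synthetic histology image plants 12 haematoxylin-dark nuclei of
~80 px² and a 10,000 px² aniline-blue collagen patch.  Counting runs the
classic chain on the CMYK black channel (background subtraction,
contrast stretch, unsharp mask, median filter, Minimum auto-threshold,
watershed, 30-200 px² size gate); collagen area thresholds the cyan
channel.
"""

import fibroswarm as fs
from fibroswarm.quant import count_nuclei, enrichment_index, scar_area

image, truth = fs.histology_fixture(n_nuclei=12, nucleus_area=80, collagen_area=10_000, seed=2)

n, labels = count_nuclei(image)
print(f"nuclei counted: {n} (planted: {truth.n_nuclei})")

res = scar_area(image)
print(f"collagen (scar) area: {res['area_px2']} px^2 "
      f"(planted: {truth.collagen_area}; {100 * res['fraction']:.2f}% of the field)")

# enrichment index on a synthetic two-channel field: MFI 200 vs 600
import numpy as np

g = np.full((128, 128), 200.0)
r = np.full((128, 128), 600.0)
print(f"enrichment index (MFI 200 vs 600): {enrichment_index(g, r):.3f} (expected 0.250)")
print("\nThe index is the fraction of mean fluorescence carried by the "
      "lineage-positive channel: 0.5 = balanced, 1.0 = pure.")
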