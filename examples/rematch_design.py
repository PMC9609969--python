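"""Rematch a 1/7-inch chip's lens with a larger chip that captures the
whole circular image field, and plan the new pixel density.

The circular image field of the original camera has the diameter of the
old chip's diagonal (1/7 inch). A chip whose *height* equals that diameter
captures the full circle; the smallest such diagonal is d1*sqrt(1+eta^2).
"""

from circam import rematch

for mode in ("preserve_density", "equal_count"):
    res = rematch(d1=1 / 7, aspect=4 / 3, sigma1=1.0, mode=mode)
    print(f"mode = {mode}")
    print(f"  minimum rematched diagonal : {res.min_diagonal:.4f} inch (5/21)")
    print(f"  selected standard format   : {res.selected_format} inch")
    print(f"  pixel density sigma2/sigma1: {res.pixel_density_2:.2f}")
    print(f"  pixel count ratio N2/N1    : {res.pixel_ratio:.2f}")
    print(f"  linear resolution change   : {100 * res.resolution_change:+.0f}%")

# preserve_density keeps detail but ~2.78x the pixels to move and store;
# equal_count keeps the data volume closer (1.70x) at -22% resolution.
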