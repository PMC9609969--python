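"""How much does a rectangular crop of the circular image field cost?

Two costs: area (the four circular segments outside the inscribed
rectangle are thrown away) and angle (the effective horizontal/vertical
FOV is much narrower than the advertised diagonal FOV).
"""

from circam import crop_waste_fraction, effective_fov

for label, eta in (("4:3", 4 / 3), ("16:9", 16 / 9), ("1:1", 1.0)):
    print(f"{label:>5}: {100 * crop_waste_fraction(eta):.1f}% of the circular "
          "field is wasted by the crop")

fov_h, fov_v = effective_fov(60.0, 4 / 3)
print(f"\nA '60 degree' 4:3 camera effectively sees only "
      f"{fov_h:.1f} deg (horizontal) x {fov_v:.1f} deg (vertical).")
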