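"""Isotope bookkeeping for the fertilizer labeling recipe.

Adding 0.274 umol of 98 atom-% 15N KNO3 plus 0.145 umol of 95 atom-% 15N
(NH4)2SO4 (two N per formula unit) per litre of nutrient solution shifts the
solution's delta15N by about +10 permil — provided the solution carries
about 14.8 mmol N per litre.  The mixing is computed exactly via atom
fractions against the AIR standard ratio, not by the linear approximation.
"""

from isoleaf import delta_after_label_addition

POOL_MOL_N = 14.8e-3  # mol N per litre of nutrient solution (assumption)
RECIPE = [
    (0.274e-6, 0.98),      # KNO3: 1 N per formula unit
    (2 * 0.145e-6, 0.95),  # (NH4)2SO4: 2 N per formula unit
]

for multiple, label in [(1, "+10 permil recipe"), (2, "doubled (+20 permil)")]:
    additions = [(multiple * mol, x) for mol, x in RECIPE]
    delta = delta_after_label_addition(POOL_MOL_N, 0.0, additions)
    print(f"{label:22s}: delta15N = {delta:+.3f} permil")

# mixing identity: adding material at the pool's own atom fraction changes nothing
from isoleaf import AIR_R15

x_air = AIR_R15 / (1 + AIR_R15)
unchanged = delta_after_label_addition(POOL_MOL_N, 0.0, [(1e-6, x_air)])
print(f"addition at the pool's own atom fraction: delta15N = {unchanged:+.6f} permil")
print("\nThe per-10-permil recipe is tiny in absolute N terms (~0.5 umol per "
      "litre), so the treatments change only the isotope ratio, never the "
      "nutrient supply.")
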