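"""Close a leaf analysis into a composition and take clr coordinates.

A single sample with typical grapevine leaf concentrations is closed with
the filler R (rest of the dry matter, mg/kg) and mapped to centred
log-ratios.  The clr values sum to zero: each one measures its component
relative to the geometric mean of the whole composition.
"""

import pandas as pd

from cndclr import clr_transform, to_composition

conc = pd.DataFrame(
    [{"N": 26.0, "P": 1.8, "K": 8.4, "Ca": 20.7, "Mg": 3.8, "S": 1.6,
      "B": 60.5, "Cu": 110.9, "Fe": 65.2, "Mn": 48.8, "Zn": 40.6}]
)  # macronutrients g/kg, micronutrients mg/kg

comp = to_composition(conc)
clr = clr_transform(comp)

print("composition (mg/kg):")
print(comp.round(1).to_string(index=False))
print("\nclr coordinates:")
print(clr.round(3).to_string(index=False))
print(f"\nrow sum of clr = {clr.iloc[0].sum():.2e}  (zero-sum closure)")
print("positive clr: component above the compositional geometric mean; negative: below")
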