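"""Derive critical levels and sufficiency ranges, and check recovery.

Concentration is regressed on the CND index per nutrient; the prediction at
index zero is the critical level NC, and NC ± ⅔·SD(concentration in the
reference) spans the sufficiency range.  Because the data are synthetic, the
true equilibrium concentrations are known and the recovery error is printed.
"""

from cndclr import (
    COMPONENTS,
    GroupConfig,
    build_sufficiency_table,
    compute_norms,
    generate_group,
    select_reference,
)

mean = {"N": 2.56, "P": 0.08, "K": 1.03, "Ca": 3.55, "Mg": 1.48, "S": -0.09,
        "B": -3.04, "Cu": -2.26, "Fe": -1.02, "Mn": -2.64, "Zn": -2.97}
mean["R"] = -sum(mean.values())
cfg = GroupConfig(
    group_id="demo", n=300, clr_mean=mean,
    clr_sd={c: (0.2 if c != "R" else 0.05) for c in COMPONENTS},
    yield_mean=40.0, yield_sd=3.0,
)
samples, truth = generate_group(cfg, 5)

norms = compute_norms(select_reference(samples, top_fraction=0.5))
table = build_sufficiency_table(samples, norms)

print("nutrient   NC     lower   upper    R2    true_NC  rel.err")
for nut in ("N", "P", "K", "Ca", "Mg", "Zn"):
    row = table.loc[nut]
    true_nc = truth["equilibrium_conc"][nut]
    err = row["critical_level"] / true_nc - 1.0
    print(f"{nut:>6} {row['critical_level']:8.2f} {row['lower']:7.2f} {row['upper']:7.2f} "
          f"{row['model_r2']:6.2f} {true_nc:8.2f} {err:+7.1%}")
print("\nNC is the concentration at index zero; the range half-width is 2/3 of the")
print("reference concentration SD, so NC is always the midpoint of the range")
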