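"""Screen a group for atypical samples with Mahalanobis distances.

Generates one synthetic group with two planted outliers (+6 SD shifts in two
nutrients) and runs the single-pass chi-square filter.  The planted samples
should be the ones excluded.
"""

from cndclr import COMPONENTS, GroupConfig, filter_outliers, generate_group

mean = {"N": 2.56, "P": 0.08, "K": 1.03, "Ca": 3.55, "Mg": 1.48, "S": -0.09,
        "B": -3.04, "Cu": -2.26, "Fe": -1.02, "Mn": -2.64, "Zn": -2.97}
mean["R"] = -sum(mean.values())

cfg = GroupConfig(
    group_id="demo", n=100,
    clr_mean=mean, clr_sd={c: (0.2 if c != "R" else 0.05) for c in COMPONENTS},
    yield_mean=40.0, yield_sd=3.0,
    outlier_fraction=0.02, outlier_shift=6.0,
)
samples, truth = generate_group(cfg, 7)

retained, report = filter_outliers(samples, alpha=0.05)
print(f"chi-square cutoff (df={report.df}, alpha={report.alpha}): {report.cutoff:.2f}")
print(f"planted outliers: {truth['outlier_ids']}")
print(f"excluded samples: {report.excluded_ids}")
print(f"retained {len(retained)} of {len(samples)} samples")
print("a squared distance above the cutoff marks a sample atypical for its group")
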