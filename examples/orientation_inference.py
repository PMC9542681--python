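"""Test size and shape differences among orientation groups.

Runs the whole-flower-level comparisons on the falls of a simulated
dataset: one-way ANOVA of centroid size, and permutation tests (Goodall's
F and Pillai's trace, organ-level label permutation) of the symmetric and
asymmetric shape components grouped by compass orientation and by
orientation relative to the outer spathe.
"""

import floralsym as fs

params = fs.SimulationParams.defaults(n_flowers=150, seed=3, organ_types=("fall",))
records, configs = fs.generate_dataset(params)
organs = fs.organs_table(records, configs)
dec = fs.object_symmetry_decompose(configs, fs.default_pairing("fall"))

sizes = [fs.centroid_size(c) for c in configs]
anova = fs.anova_centroid_size(sizes, organs["compass_orientation"])
print(
    f"centroid size ~ compass orientation: F_{anova.df_between},"
    f"{anova.df_within} = {anova.F:.2f}, p = {anova.p_value:.3f}"
)

for component, data in (("symmetric", dec.symmetric), ("asymmetric", dec.asymmetric)):
    for grouping in ("compass_orientation", "relative_orientation"):
        sample = fs.GroupedShapeSample(
            data, organs[grouping].to_numpy(), component,
            flower_ids=organs["flower_id"].to_numpy(),
        )
        g = fs.permutation_test(sample, "goodall_f", 10_000, seed=4)
        p = fs.permutation_test(sample, "pillai", 10_000, seed=4)
        print(
            f"{component:10s} x {grouping:21s}: Goodall's F = {g.observed:.3f} "
            f"(p = {g.p_value:.4f}), Pillai = {p.observed:.4f} "
            f"(p = {p.p_value:.4f})"
        )

print(
    "\n-> under the default simulation conditions the compass-orientation "
    "tests reject (a consistent environmental gradient shapes the organs "
    "by compass direction) while the relative-orientation tests do not "
    "(no anatomical-position effect was injected)."
)
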