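"""Draw shape-change diagrams and a CV score plot with confidence ellipses.

Computes the falls' mean asymmetric shape, warps the template outline
through a thin-plate spline with the shape change exaggerated 15-fold,
and plots CV1-CV2 scores of the asymmetric component grouped by compass
orientation with 95% confidence ellipses for the group means.
"""

import pathlib

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

import floralsym as fs

params = fs.SimulationParams.defaults(n_flowers=150, seed=5, organ_types=("fall",))
records, configs = fs.generate_dataset(params)
organs = fs.organs_table(records, configs)
dec = fs.object_symmetry_decompose(configs, fs.default_pairing("fall"))

# mean asymmetric shape change, exaggerated 15x on the consensus outline
mean_asym = dec.asymmetric.mean(axis=0).reshape(18, 2)
outline_order = list(range(18)) + [0]
outline = dec.consensus[outline_order]
spec = fs.WarpSpec(
    reference=dec.consensus,
    target=dec.consensus + mean_asym,
    outline=outline,
    exaggeration=15.0,
)
fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 5))
fs.shape_difference_plot(spec, ax=ax1)
ax1.set_title("mean organ asymmetry, 15x exaggerated")

sample = fs.GroupedShapeSample(
    dec.asymmetric, organs["compass_orientation"].to_numpy(), "asymmetric"
)
result = fs.cva(sample)
_, ellipses = fs.cv_ellipse_plot(result, ax=ax2)
ax2.set_title("CV scores by compass orientation")

out = "example_output/shape_diagrams.png"
pathlib.Path("example_output").mkdir(exist_ok=True)
fig.savefig(out, dpi=150, bbox_inches="tight")
plt.close(fig)
print(f"saved figure to {out}")
print("\nellipse parameters (CV1-CV2, 95% confidence for group means):")
print(ellipses.round(3).to_string(index=False))
print(
    "\n-> landmark displacements in the left panel are 15x the actual mean "
    "difference; well-separated ellipses in the right panel indicate "
    "compass-orientation groups with distinct mean asymmetric shapes."
)
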