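"""Split fall shapes into symmetric and asymmetric components.

Superimposes each fall jointly with its reflected-and-relabeled copy and
decomposes its shape into a symmetric component (the bilaterally
symmetric 'target' form) and an asymmetric component (the left-right
deviation). The mean asymmetric component across all falls is the
directional asymmetry of the individual organ - the 'pinwheel' signal.
"""

import numpy as np

import floralsym as fs

params = fs.SimulationParams.defaults(n_flowers=100, seed=2, organ_types=("fall",))
records, configs = fs.generate_dataset(params)
pairing = fs.default_pairing("fall")
res = fs.object_symmetry_decompose(configs, pairing)

print(f"decomposed {len(configs)} falls (joint GPA, {res.n_iterations} iterations)")
additivity = np.abs(res.symmetric + res.asymmetric - res.tangent).max()
print(f"additivity residual (symmetric + asymmetric - original): {additivity:.2e}")

mean_asym = res.asymmetric.mean(axis=0)
rms_asym = np.sqrt((np.linalg.norm(res.asymmetric, axis=1) ** 2).mean())
print(f"\nmean asymmetric component norm: {np.linalg.norm(mean_asym):.5f}")
print(f"root-mean-square per-organ asymmetry: {rms_asym:.5f}")
print(
    "-> a mean asymmetry well above zero is directional asymmetry of the "
    "individual organ: every fall leans the same way, which at the "
    "whole-flower level produces a pinwheel pattern. The RMS value also "
    "contains the fluctuating (random) part of asymmetry."
)
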