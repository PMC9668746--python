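"""Render a dominant-clone map with the CCF / cell-density masking rule.

Tiles show their most prevalent tumour clone only where that clone exceeds
25% of cells and the local density exceeds 300 cells/mm²; everything else is
masked with a recorded reason. The map is printed as ASCII art and, when
matplotlib is available, written to dominant_clones.png.
"""

import numpy as np

import clonemapper as cm
from clonemapper.benchmark import run_default_benchmark
from clonemapper.postprocess import dominant_clone_table

result = run_default_benchmark(
    seed=7,
    sim_config=cm.SimConfig(extent_um=(2500.0, 2500.0), seed=7),
    model_config=cm.ModelConfig(steps=800, seed=7),
    n_regions=8,
)
cmap = result.clone_map
field = cm.dominant_clone_map(cmap)

symbols = {"": "."}
for i, comp in enumerate(cmap.tumour_components):
    symbols[comp] = str(i + 1)
img = np.array([symbols[l] for l in field.labels]).reshape(
    cmap.grid.ny, cmap.grid.nx
)
print("dominant clones ('.' = masked):")
for row in img[::-1]:  # y increases upward
    print("".join(row))

tab = dominant_clone_table(field)
print(tab["mask_reason"].value_counts().rename("tiles").to_string())

try:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    codes = np.array(
        [
            0 if l == "" else cmap.tumour_components.index(l) + 1
            for l in field.labels
        ]
    ).reshape(cmap.grid.ny, cmap.grid.nx)
    plt.figure(figsize=(5, 5))
    plt.imshow(codes, origin="lower", cmap="tab10", interpolation="nearest")
    plt.title("dominant clone per 100 µm tile")
    plt.savefig("dominant_clones.png", dpi=150)
    print("wrote dominant_clones.png")
except ImportError:
    pass
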