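"""Phenotype statistics over clone territories.

Shows the three statistical tools on small synthetic inputs: rank-sum
differential expression between two territories with BH/fold-change gating,
Poisson GLMM cell-type enrichment against clone fraction with a region random
effect, and the Fisher exact clone-histology association with Bonferroni
correction.
"""

import numpy as np
import pandas as pd

import clonemapper as cm
from clonemapper.io import CellTable
from clonemapper.stats import (
    TerritoryAssignment,
    differential_expression,
    histology_association,
)

rng = np.random.default_rng(0)

# --- differential expression: gene g0 spiked 3x in territory A ---------------
n = 200
genes = [f"g{i}" for i in range(8)]
mu = np.tile(rng.uniform(2, 6, len(genes)), (n, 1))
mu[: n // 2, 0] *= 3.0
cells = CellTable(
    pd.DataFrame({"x": np.zeros(n), "y": np.zeros(n)}),
    gene_counts=pd.DataFrame(rng.poisson(mu), columns=genes),
)
labels = np.array(["A"] * (n // 2) + ["B"] * (n // 2), dtype=object)
assignment = TerritoryAssignment(labels, np.zeros(n, int))
de = differential_expression(cells, assignment, "A", "B")
print("differential expression (A vs B):")
print(de[["log2_fc", "q", "significant"]].round(3).to_string())

# --- GLMM: myeloid cells enriched 2x with clone A fraction -------------------
n_regions = 20
frac = pd.DataFrame(
    {"cloneA": rng.uniform(0, 1, n_regions)},
    index=[f"r{i}" for i in range(n_regions)],
)
total = pd.Series(500, index=frac.index)
counts = pd.DataFrame(
    {"myeloid": rng.poisson(total * 0.05 * np.exp(np.log(2) * frac["cloneA"]))},
    index=frac.index,
)
glmm = cm.celltype_glmm(counts, frac, total, seed=0)
print("\ncell-type enrichment GLMM:")
print(glmm.summary[["beta_mean", "ci_lo", "ci_hi", "q", "converged"]]
      .round(3).to_string())

# --- clone-histology association --------------------------------------------
regions = pd.DataFrame(
    {
        "dominant_clone": ["A"] * 7 + ["B"] * 7,
        "lesion": ["DCIS"] * 6 + ["invasive"] + ["invasive"] * 6 + ["DCIS"],
        "grade": list("LHLHLHL") + list("HLHLHLH"),
    },
    index=[f"r{i}" for i in range(14)],
)
assoc = histology_association(regions)
print("\nclone-histology association (Fisher exact, Bonferroni):")
print(assoc.round(4).to_string())
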