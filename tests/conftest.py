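"""Shared fixtures: small panels, trees, and a cached small-scale fitted benchmark."""

from __future__ import annotations

import pandas as pd
import pytest

import clonemapper as cm
from clonemapper.benchmark import run_default_benchmark


@pytest.fixture(scope="session")
def tree():
    return cm.default_tree()


@pytest.fixture(scope="session")
def panel(tree):
    return cm.default_panel(n_loci=25, tree=tree)


@pytest.fixture(scope="session")
def genotype(tree, panel):
    return cm.build_genotype_matrix(tree, panel)


@pytest.fixture
def toy_panel():
    """2 SNV loci (4 probes) on a 2-clone linear tree."""
    return cm.ProbePanel(
        pd.DataFrame(
            {
                "probe_id": ["L0_mut", "L0_wt", "L1_mut", "L1_wt"],
                "locus_id": ["L0", "L0", "L1", "L1"],
                "allele_class": ["mutant", "wildtype", "mutant", "wildtype"],
                "branch_id": ["a", "a", "b", "b"],
                "barcode": ["AAAAA", "CCCCC", "GGGGG", "TTTTT"],
            }
        )
    )


@pytest.fixture
def toy_tree():
    return cm.CloneTree(parent={"a": None, "b": "a"})


@pytest.fixture(scope="session")
def small_benchmark():
    """Scaled-down end-to-end benchmark (2.5 x 2.5 mm, shorter optimization)."""
    return run_default_benchmark(
        seed=7,
        sim_config=cm.SimConfig(extent_um=(2500.0, 2500.0), seed=7),
        model_config=cm.ModelConfig(steps=800, seed=7),
        n_regions=8,
    )


@pytest.fixture(scope="session")
def halfsplit_benchmark():
    """Two-clone vertical-split tissue with a fitted map (boundary benchmark)."""
    tree = cm.CloneTree(parent={"a": None, "b": "a"})
    panel = cm.default_panel(n_loci=10, tree=tree)
    return run_default_benchmark(
        seed=5,
        sim_config=cm.SimConfig(
            extent_um=(2000.0, 2000.0), territory_mode="half_split", seed=5,
            replicate_count=1,
        ),
        model_config=cm.ModelConfig(steps=1200, seed=5),
        n_regions=4,
        tree=tree,
        panel=panel,
    )
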