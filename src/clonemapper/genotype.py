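"""Somatic phylogeny to expected-allele-copies matrix.

A subclone's genotype is the set of branch mutations accumulated from the tree
root down to the subclone's node, so every descendant carries a superset of its
ancestor's mutant loci. The genotype matrix G[probe, clone] holds the expected
copies per cell of the probed allele; it is what the clone model and the VAF
imputation consume. Without a copy-number table, SNV loci are assumed
heterozygous diploid (total copies C = 2, mutant multiplicity m = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import COPY_NUMBER, MUTANT, WILDTYPE, ProbePanel, ValidationError

NORMAL_CLONE = "normal"


@dataclass
class CloneTree:
    """Rooted clone phylogeny; each branch is identified by its child clone.

    ``parent`` maps clone_id -> parent clone_id (root maps to None). Mutations
    are attached to branches via the probe panel's branch_id column, so the tree
    itself stores topology only.
    """

    parent: dict[str, str | None]
    colors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [c for c, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {roots}")
        for c in self.parent:
            if self._path_to_root(c) is None:
                raise ValidationError(f"cycle or dangling parent at clone {c}")

    def _path_to_root(self, clone: str) -> list[str] | None:
        path, seen = [], set()
        cur: str | None = clone
        while cur is not None:
            if cur in seen or cur not in self.parent:
                return None
            seen.add(cur)
            path.append(cur)
            cur = self.parent[cur]
        return path

    @property
    def root(self) -> str:
        return next(c for c, p in self.parent.items() if p is None)

    @property
    def clones(self) -> list[str]:
        return list(self.parent)

    def branches_on_path(self, clone: str) -> set[str]:
        """Branch ids (child-clone ids) on the root -> clone path, incl. the trunk."""
        path = self._path_to_root(clone)
        assert path is not None
        return set(path)  # the branch into the root carries trunk mutations, if any

    def descendants(self, clone: str) -> set[str]:
        out = {clone}
        changed = True
        while changed:
            changed = False
            for c, p in self.parent.items():
                if p in out and c not in out:
                    out.add(c)
                    changed = True
        return out


def read_clone_tree(path: str | Path) -> CloneTree:
    """Read a tree from 2/3-column TSV (clone, parent[, color]) or Newick.

    In the TSV form the root's parent cell is empty or 'NA'. In Newick form the
    node labels are clone ids.
    """
    path = Path(path)
    if path.suffix in {".nwk", ".newick", ".tree"}:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        parent: dict[str, str | None] = {}
        colors: dict[str, str] = {}
        for node in tree.preorder_node_iter():
            label = node.taxon.label if node.taxon else node.label
            if label is None:
                raise ValidationError("unlabelled node in Newick tree")
            pl = None
            if node.parent_node is not None:
                p = node.parent_node
                pl = p.taxon.label if p.taxon else p.label
            parent[str(label)] = None if pl is None else str(pl)
        return CloneTree(parent, colors)
    df = pd.read_csv(path, sep="\t")
    parent = {}
    colors = {}
    for _, row in df.iterrows():
        p = row["parent"]
        parent[str(row["clone"])] = (
            None if pd.isna(p) or str(p) in {"", "NA", "none"} else str(p)
        )
        if "color" in df.columns and not pd.isna(row.get("color")):
            colors[str(row["clone"])] = str(row["color"])
    return CloneTree(parent, colors)


def read_copy_numbers(path: str | Path) -> pd.DataFrame:
    """TSV with columns locus_id, clone_id, total_cn, mutant_cn."""
    df = pd.read_csv(path, sep="\t")
    df["locus_id"] = df["locus_id"].astype(str)
    df["clone_id"] = df["clone_id"].astype(str)
    return df


@dataclass
class GenotypeMatrix:
    """Expected copies per cell of each probed allele in each clone.

    ``G`` is probes × clones (ordering given by ``probe_ids`` / ``clones``);
    the clone list always contains the designated normal clone. ``panel`` is
    retained so mutant/wildtype pairing and locus lookup stay available to the
    model and the VAF computations.
    """

    G: np.ndarray
    probe_ids: list[str]
    clones: list[str]
    panel: ProbePanel
    normal_clone: str = NORMAL_CLONE

    def __post_init__(self) -> None:
        if self.G.shape != (len(self.probe_ids), len(self.clones)):
            raise ValidationError("G shape does not match probe/clone lists")
        if (self.G < 0).any():
            raise ValidationError("negative expected allele copies")
        if self.normal_clone not in self.clones:
            raise ValidationError("normal clone missing from clone list")
        k0 = self.clones.index(self.normal_clone)
        pmap = self.panel.data.set_index("probe_id")["allele_class"]
        mut_rows = [i for i, p in enumerate(self.probe_ids) if pmap[p] == MUTANT]
        if mut_rows and self.G[mut_rows, k0].any():
            raise ValidationError("normal clone carries mutant alleles")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def tumour_clones(self) -> list[str]:
        return [c for c in self.clones if c != self.normal_clone]

    def probe_index(self, probe_id: str) -> int:
        return self.probe_ids.index(probe_id)

    def clone_index(self, clone: str) -> int:
        return self.clones.index(clone)

    def locus_of_probe(self) -> list[str]:
        lmap = self.panel.data.set_index("probe_id")["locus_id"]
        return [str(lmap[p]) for p in self.probe_ids]

    def snv_pairs(self) -> list[tuple[str, int, int]]:
        """(locus_id, mutant row, wildtype row) for every paired SNV locus."""
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        return [
            (locus, idx[m], idx[w])
            for locus, m, w in self.panel.pairs()
            if m in idx and w in idx
        ]


def build_genotype_matrix(
    tree: CloneTree,
    panel: ProbePanel,
    copy_numbers: pd.DataFrame | None = None,
    ploidy_default: int = 2,
) -> GenotypeMatrix:
    """Expand tree topology + branch assignments into the genotype matrix.

    Clone k carries the mutant allele of locus l iff l's branch lies on the
    root→k path. SNV loci default to C = ``ploidy_default``, m = 1 unless the
    copy-number table overrides them; copy_number-class probes receive the total
    copy number directly.
    """
    clones = tree.clones + [NORMAL_CLONE]
    tree_branches = set(tree.clones)
    cn: dict[tuple[str, str], tuple[float, float]] = {}
    if copy_numbers is not None:
        for _, row in copy_numbers.iterrows():
            C, m = float(row["total_cn"]), float(row["mutant_cn"])
            if C < 0 or m < 0:
                raise ValidationError(
                    f"negative copy number at ({row['locus_id']}, {row['clone_id']})"
                )
            if m > C:
                raise ValidationError(
                    f"mutant_cn > total_cn at ({row['locus_id']}, {row['clone_id']})"
                )
            cn[(str(row["locus_id"]), str(row["clone_id"]))] = (C, m)

    carried = {k: tree.branches_on_path(k) for k in tree.clones}
    carried[NORMAL_CLONE] = set()

    probe_ids = list(panel.data["probe_id"])
    G = np.zeros((len(probe_ids), len(clones)))
    for i, (_, probe) in enumerate(panel.data.iterrows()):
        locus = str(probe["locus_id"])
        branch = str(probe["branch_id"])
        if branch not in tree_branches and probe["allele_class"] != COPY_NUMBER:
            raise ValidationError(f"branch_id {branch!r} of probe "
                                  f"{probe['probe_id']!r} not in tree")
        for k, clone in enumerate(clones):
            C, m = cn.get((locus, clone), (float(ploidy_default), 1.0))
            has_mut = clone != NORMAL_CLONE and branch in carried[clone]
            if probe["allele_class"] == MUTANT:
                G[i, k] = m if has_mut else 0.0
            elif probe["allele_class"] == WILDTYPE:
                G[i, k] = C - m if has_mut else C
            else:  # copy-number target reports total copies
                G[i, k] = cn.get((locus, clone), (float(ploidy_default), 0.0))[0]
    return GenotypeMatrix(G, probe_ids, clones, panel)


def expected_vaf(
    G: GenotypeMatrix, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Population VAF of each paired SNV locus under a clone-fraction mixture.

    VAF_l = Σ_k w_k G_mut[l,k] / Σ_k w_k (G_mut[l,k] + G_wt[l,k]).
    Returns (vaf, undefined_mask, locus_ids); a locus deleted in every weighted
    clone (0/0) yields 0 with its undefined flag set.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (G.n_clones,):
        raise ValidationError(
            f"weight vector length {w.shape} does not match {G.n_clones} clones"
        )
    if (w < -1e-12).any():
        raise ValidationError("negative clone weight")
    s = w.sum()
    if not np.isclose(s, 1.0, atol=1e-6):
        raise ValidationError(f"weights sum to {s}, expected 1")
    pairs = G.snv_pairs()
    vaf = np.zeros(len(pairs))
    undefined = np.zeros(len(pairs), dtype=bool)
    loci = []
    for i, (locus, mi, wi) in enumerate(pairs):
        loci.append(locus)
        num = float(w @ G.G[mi])
        den = float(w @ (G.G[mi] + G.G[wi]))
        if den <= 0:
            undefined[i] = True
            vaf[i] = 0.0
        else:
            vaf[i] = num / den
    return vaf, undefined, loci
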