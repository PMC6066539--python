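"""Co-expression module detection, eigengenes and meta-modules.

Genes surviving a variation filter are clustered by correlation of their
log2(FPKM + 1) profiles (unsigned network, dissimilarity 1 - |r|; a
topological-overlap variant is available).  An average-linkage tree is
cut with a deterministic tree-structured dynamic cut subject to a minimum
module size; each module is summarised by its eigengene (first principal
component of the standardised within-module expression) and modules whose
eigengenes are mutually close (1 - r <= 0.2 by default) group into
meta-modules.  With only six samples the null distribution of |r|
between unrelated genes is proportional to (1 - r^2) — P(|r| > 0.75) is
already ~9% per pair — so the default cut height keeps only very
tightly correlated branches (|r| >= 0.95, chance ~0.2%) and the
module-size floor discards the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionStudy, log

__all__ = [
    "ModulePartition",
    "EigengeneSet",
    "MetaModuleGrouping",
    "variation_filter",
    "gene_dissimilarity",
    "cluster_and_cut",
    "compute_eigengenes",
    "group_metamodules",
]


def variation_filter(study: ExpressionStudy, min_range: float) -> ExpressionStudy:
    """Keep genes whose FPKM range across all samples strictly exceeds
    ``min_range``."""
    vals = study.fpkm
    rng = vals.max(axis=1) - vals.min(axis=1)
    keep = rng > min_range
    log.info("variation filter: %d/%d genes kept", int(keep.sum()), len(keep))
    return study.subset_genes(study.genes[keep])


def gene_dissimilarity(
    study: ExpressionStudy, method: str = "cor", power: float = 6.0
) -> pd.DataFrame:
    """Gene x gene dissimilarity on log2(FPKM + 1) profiles.

    ``cor``: d = 1 - |Pearson r| (unsigned).  ``tom``: adjacency
    a = |r|^power; topological overlap
    w_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k_i = sum_u a_iu, d = 1 - w.  Symmetric, zero diagonal, values in
    [0, 1].
    """
    if study.n_samples < 3:
        raise ValueError("need >= 3 samples for correlation dissimilarity")
    X = study.log2_matrix().to_numpy()
    sd = X.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = study.genes[sd == 0][0]
        raise ValueError(
            f"zero-variance gene {bad!r}; apply variation_filter first"
        )
    r = np.corrcoef(X)
    a = np.abs(np.clip(r, -1.0, 1.0))
    if method == "cor":
        d = 1.0 - a
    elif method == "tom":
        a = a**power
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        numer = a @ a + a
        denom = np.minimum.outer(k, k) + 1.0 - a
        omega = numer / denom
        d = 1.0 - omega
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(d, index=study.genes, columns=study.genes)


@dataclass
class ModulePartition:
    """Gene -> module assignment (module 0 = unassigned) with its tree."""

    assignment: pd.Series
    linkage: np.ndarray | None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = self.sizes()
        min_size = self.params.get("min_module_size")
        if min_size is not None:
            small = {m: s for m, s in sizes.items() if m != 0 and s < min_size}
            if small:
                raise AssertionError(f"modules below size floor: {small}")
        labels = sorted(m for m in sizes if m != 0)
        if labels != list(range(1, len(labels) + 1)):
            raise AssertionError(f"module ids not dense from 1: {labels}")

    def sizes(self) -> dict[int, int]:
        return self.assignment.value_counts().sort_index().to_dict()

    @property
    def module_ids(self) -> list[int]:
        return sorted(m for m in set(self.assignment) if m != 0)

    def genes_in(self, module: int) -> pd.Index:
        return self.assignment.index[self.assignment == module]


def cluster_and_cut(
    dissim: pd.DataFrame,
    min_module_size: int,
    cut_height: float = 0.05,
    split_gap: float = 0.5,
) -> ModulePartition:
    """Average-linkage clustering with a deterministic tree-structured cut.

    Branches whose internal merges all lie at or below ``cut_height``
    are module candidates; a candidate splits recursively at its top
    merge when that merge sits a significant gap above both children
    (gap >= ``split_gap`` x merge height) and both children satisfy the
    size floor.  Candidates below ``min_module_size`` go to module 0.
    Modules are numbered 1.. by decreasing size (ties by smallest gene
    index); linkage ties are resolved by scipy's deterministic
    nearest-neighbour chain over the input gene order.
    """
    genes = dissim.index
    n = len(genes)
    if n < min_module_size:
        return ModulePartition(
            pd.Series(0, index=genes),
            None,
            {"min_module_size": min_module_size, "cut_height": cut_height},
        )
    Z = hierarchy.linkage(squareform(dissim.to_numpy(), checks=False), method="average")
    root = hierarchy.to_tree(Z)

    clusters: list[list[int]] = []

    def leaves(node) -> list[int]:
        return node.pre_order(lambda x: x.id)

    def harvest(node) -> None:
        """Recursively split a candidate branch at significant height gaps."""
        if node.is_leaf() or node.get_count() < 2 * min_module_size:
            clusters.append(leaves(node))
            return
        L, R = node.get_left(), node.get_right()
        child_top = max(L.dist, R.dist)
        gap = node.dist - child_top
        if (
            node.dist > 0
            and gap >= split_gap * node.dist
            and L.get_count() >= min_module_size
            and R.get_count() >= min_module_size
        ):
            harvest(L)
            harvest(R)
        else:
            clusters.append(leaves(node))

    def descend(node) -> None:
        """Find maximal branches fully below the cut height."""
        if node.dist <= cut_height:
            if node.get_count() >= min_module_size:
                harvest(node)
            return
        descend(node.get_left())
        descend(node.get_right())

    descend(root)

    assignment = pd.Series(0, index=genes, dtype=int)
    order = sorted(clusters, key=lambda c: (-len(c), min(c)))
    mid = 1
    for members in order:
        if len(members) >= min_module_size:
            assignment.iloc[members] = mid
            mid += 1
    part = ModulePartition(
        assignment,
        Z,
        {
            "min_module_size": min_module_size,
            "cut_height": cut_height,
            "split_gap": split_gap,
        },
    )
    log.info("modules: %d found, %d genes unassigned", mid - 1,
             int((assignment == 0).sum()))
    return part


@dataclass
class EigengeneSet:
    """Module eigengenes: unit-norm first right singular vectors.

    ``eigengenes`` is modules x samples; orientation is fixed so each
    eigengene correlates non-negatively with its module's mean
    standardised profile.
    """

    eigengenes: pd.DataFrame
    explained_variance: pd.Series
    orientation: pd.Series

    @property
    def module_ids(self) -> list[int]:
        return list(self.eigengenes.index)


def compute_eigengenes(
    study: ExpressionStudy, partition: ModulePartition
) -> EigengeneSet:
    """First principal component of each module's standardised expression."""
    logm = study.log2_matrix()
    rows, ev, orient = {}, {}, {}
    for m in partition.module_ids:
        sub = logm.loc[partition.genes_in(m)].to_numpy()
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        if (sd == 0).any():
            raise ValueError(f"zero-variance gene in module {m}")
        Xs = (sub - mu) / sd
        U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        v = Vt[0]
        mean_profile = Xs.mean(axis=0)
        sign = 1.0
        c = np.dot(v, mean_profile)
        if c < 0:
            sign = -1.0
        rows[m] = sign * v
        ev[m] = float(S[0] ** 2 / np.sum(S**2))
        orient[m] = sign
    eg = pd.DataFrame(rows, index=study.fpkm.columns).T
    eg.index.name = "module"
    return EigengeneSet(eg, pd.Series(ev, name="explained_variance"),
                        pd.Series(orient, name="orientation"))


@dataclass
class MetaModuleGrouping:
    """Module -> meta-module labels from eigengene clustering."""

    labels: pd.Series  # module id -> meta-module letter
    dissimilarity: pd.DataFrame  # 1 - r between eigengenes
    cut: float
    linkage: np.ndarray | None = None

    def members(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for mod, lab in self.labels.items():
            out.setdefault(lab, []).append(mod)
        return out

    def solo_modules(self) -> list[int]:
        return [mods[0] for mods in self.members().values() if len(mods) == 1]


def group_metamodules(eigs: EigengeneSet, cut: float = 0.2) -> MetaModuleGrouping:
    """Group modules whose eigengene dissimilarity (1 - Pearson r) stays
    within ``cut`` under average linkage; singleton groups are solo
    modules."""
    ids = eigs.module_ids
    if not ids:
        raise ValueError("no modules to group")
    E = eigs.eigengenes.to_numpy()
    if len(ids) == 1:
        lab = pd.Series(["A"], index=ids)
        d = pd.DataFrame([[0.0]], index=ids, columns=ids)
        return MetaModuleGrouping(lab, d, cut)
    r = np.corrcoef(E)
    d = 1.0 - np.clip(r, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    flat = hierarchy.fcluster(Z, t=cut, criterion="distance")
    # letter labels in order of each group's smallest module id
    first_seen: dict[int, int] = {}
    for mod, g in zip(ids, flat):
        first_seen.setdefault(g, mod)
    ordered = sorted(first_seen, key=lambda g: first_seen[g])
    letter = {g: chr(ord("A") + i) for i, g in enumerate(ordered)}
    labels = pd.Series([letter[g] for g in flat], index=ids, name="metamodule")
    dd = pd.DataFrame(d, index=ids, columns=ids)
    log.info("meta-modules: %d groups from %d modules", len(ordered), len(ids))
    return MetaModuleGrouping(labels, dd, cut, Z)
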