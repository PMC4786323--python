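"""Population-genetic analyses on the catalog genotype matrix.

Implements the genotype p-distance (0 for identical genotypes, 0.5 for
homozygote vs heterozygote, 1 for opposite homozygotes, averaged over
shared loci), neighbor-joining tree construction with locus-resampling
bootstrap, covariance-matrix PCA, per-accession heterozygosity per Kb of
RAD tag sequence, within-group nucleotide diversity pi at each SNP, and
the loss-of-diversity statistic LOD = 1 - pi_cultivated/pi_wild used to
scan for loci fixed by domestication (LOD = 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import GenotypeMatrix, classify_substitution
from .simulate import TAG_LENGTH


# ---------------------------------------------------------------------------
# genotype p-distance


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    n_shared: np.ndarray  # loci compared per pair

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.labels.index(p) for p in pair)
        return float(self.values[i, j])


def _pair_distance_sums(values: np.ndarray):
    """Per-pair summed genotype distances and shared-locus counts.

    ``values`` is accessions x loci with entries 0/0.5/1 and NaN for
    missing; |v_i - v_j| reproduces the 0/0.5/1 genotype distance rule,
    including distance 0 for het vs het.
    """
    n = values.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    diffs = np.empty((len(pairs), values.shape[1]))
    for k, (i, j) in enumerate(pairs):
        diffs[k] = np.abs(values[i] - values[j])
    valid = ~np.isnan(diffs)
    sums = np.where(valid, diffs, 0.0).sum(axis=1)
    counts = valid.sum(axis=1)
    return pairs, sums, counts


def pairwise_distance_matrix(
    matrix: GenotypeMatrix, scale: str = "snp"
) -> DistanceMatrix:
    """Mean pairwise genotype distance over loci genotyped in both accessions.

    ``scale='snp'`` divides by the shared-locus count (distances in [0, 1]);
    ``scale='nt'`` divides by the shared tag length (41 nt per locus), a
    constant rescaling that leaves the NJ topology unchanged.
    """
    labels = matrix.accessions
    if len(labels) < 2:
        raise ValueError("need at least two accessions")
    values = matrix.dosage_values()
    pairs, sums, counts = _pair_distance_sums(values)
    n = len(labels)
    D = np.zeros((n, n))
    N = np.zeros((n, n), dtype=int)
    for (i, j), s, c in zip(pairs, sums, counts):
        if c == 0:
            raise ValueError(
                f"no shared genotyped loci for pair ({labels[i]}, {labels[j]})"
            )
        denom = c * TAG_LENGTH if scale == "nt" else c
        D[i, j] = D[j, i] = s / denom
        N[i, j] = N[j, i] = c
    return DistanceMatrix(labels=list(labels), values=D, n_shared=N)


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    """Node of an unrooted tree (stored rooted at a trifurcation)."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def to_newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = (
                    f"{node.support:g}"
                    if with_support and node.support is not None
                    else ""
                )
                body = f"({inner}){label}"
            if top:
                return body
            return f"{body}:{node.length:.10g}"

        return fmt(self, True) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalised as the side not
        containing the alphabetically first leaf."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        parts: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self and 2 <= len(below) <= len(all_leaves) - 2:
                side = all_leaves - below if anchor in below else below
                parts.add(side)
            return below

        walk(self)
        return parts

    def patristic_distances(self) -> pd.DataFrame:
        """Leaf-to-leaf path lengths (sums of branch lengths)."""
        names = sorted(self.leaf_names())
        dist = pd.DataFrame(0.0, index=names, columns=names)

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            sides = [walk(c) for c in node.children]
            for c, side in zip(node.children, sides):
                for k in side:
                    side[k] += c.length
            for s1, s2 in itertools.combinations(sides, 2):
                for a, da in s1.items():
                    for b, db in s2.items():
                        dist.at[a, b] = dist.at[b, a] = da + db
            merged = {}
            for side in sides:
                merged.update(side)
            return merged

        walk(self)
        return dist


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining (Q-criterion agglomeration).

    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch, preserving the path length through the join; on
    additive (four-point) distance matrices the input tree is recovered
    exactly, clamping never firing.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    D = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)  # first minimum
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        d_ij = sub[i_, j_]
        li = d_ij / 2 + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = d_ij - li
        li, lj = clamp(li, lj)
        parent = TreeNode(children=[nodes[ai], nodes[aj]])
        nodes[ai].length = li
        nodes[aj].length = lj
        # distances from the new node to the others
        new_row = np.empty(len(D) + 1)
        for k in active:
            new_row[k] = (D[ai, k] + D[aj, k] - d_ij) / 2
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b, c = active
    # three-point closed form
    la = (D[a, b] + D[a, c] - D[b, c]) / 2
    lb = D[a, b] - la
    lc = D[a, c] - la
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(length, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    tree: TreeNode  # reference tree with supports attached
    supports: dict[frozenset, float]  # bipartition -> % of replicates
    n_replicates: int
    n_redrawn: int = 0

    def clade_support(self, members: Sequence[str]) -> float:
        """Support (%) for the bipartition separating ``members``; leaf and
        near-trivial splits are always present (100%)."""
        leaves = frozenset(self.tree.leaf_names())
        side = frozenset(members)
        if not side <= leaves:
            raise ValueError("members not in tree")
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            return 100.0
        if min(leaves) in side:
            side = leaves - side
        return self.supports.get(side, 0.0)


def _distance_from_values(values: np.ndarray, labels: list[str]) -> DistanceMatrix:
    pairs, sums, counts = _pair_distance_sums(values)
    n = len(labels)
    D = np.zeros((n, n))
    N = np.zeros((n, n), dtype=int)
    for (i, j), s, c in zip(pairs, sums, counts):
        if c == 0:
            raise ValueError("undefined pair distance")
        D[i, j] = D[j, i] = s / c
        N[i, j] = N[j, i] = c
    return DistanceMatrix(labels=labels, values=D, n_shared=N)


def bootstrap_support(
    matrix: GenotypeMatrix,
    n_reps: int = 1000,
    seed: int = 0,
    max_redraws: int = 1000,
) -> BootstrapResult:
    """Locus-resampling bootstrap of the NJ tree.

    Loci are resampled with replacement ``n_reps`` times; each replicate
    rebuilds the distance matrix and NJ tree, and support is the
    percentage of replicates containing each bipartition of the reference
    tree. Replicates in which some pair shares no genotyped locus are
    redrawn (counted in ``n_redrawn``).
    """
    labels = matrix.accessions
    values = matrix.dosage_values()
    ref_tree = neighbor_joining(pairwise_distance_matrix(matrix))
    ref_parts = ref_tree.bipartitions()
    counts = {part: 0 for part in ref_parts}
    rng = np.random.default_rng(seed)
    L = values.shape[1]
    n_redrawn = 0
    done = 0
    while done < n_reps:
        idx = rng.integers(0, L, size=L)
        try:
            dm = _distance_from_values(values[:, idx], labels)
        except ValueError:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        parts = neighbor_joining(dm).bipartitions()
        for part in ref_parts & parts:
            counts[part] += 1
        done += 1
    supports = {part: 100.0 * c / n_reps for part, c in counts.items()}

    def annotate(node: TreeNode, root: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c, root) for c in node.children))
        leaves = frozenset(root.leaf_names())
        if node is not root and 2 <= len(below) <= len(leaves) - 2:
            side = leaves - below if min(leaves) in below else below
            node.support = supports.get(side)
        return below

    annotate(ref_tree, ref_tree)
    return BootstrapResult(
        tree=ref_tree, supports=supports, n_replicates=n_reps, n_redrawn=n_redrawn
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # descending
    coordinates: pd.DataFrame  # accessions x components
    variance_fractions: np.ndarray


def pca_coordinates(matrix: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA by eigendecomposition of the accession covariance matrix.

    Genotypes are coded 0/0.5/1 (alt-allele dosage halved), missing values
    filled with the locus mean, loci centred; all-missing loci are dropped.
    Coordinates are eigenvectors scaled by the square root of their
    eigenvalues.
    """
    if len(matrix.accessions) < 2 or matrix.n_loci < 1:
        raise ValueError("need >=2 accessions and >=1 locus")
    X = matrix.dosage_values()  # accessions x loci
    keep = ~np.all(np.isnan(X), axis=0)
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("all loci entirely missing")
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    Xc = X - X.mean(axis=0)
    cov = Xc @ Xc.T / max(X.shape[1] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    k = min(n_components, len(evals))
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    return PcaResult(
        eigenvalues=evals,
        coordinates=pd.DataFrame(
            coords,
            index=matrix.accessions,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        variance_fractions=fractions,
    )


# ---------------------------------------------------------------------------
# heterozygosity


@dataclass
class HeterozygosityRecord:
    accession: str
    n_het: int
    l_rad_genome: int  # nt of SNP-bearing tag sequence genotyped
    per_kb: float


def heterozygosity_rate(
    matrix: GenotypeMatrix, accession: str, tag_length: int = TAG_LENGTH
) -> HeterozygosityRecord:
    """Heterozygous calls per Kb of genotyped RAD tag sequence
    (H = N_hSNP / L_RAD-genome, L = 41 nt per genotyped locus)."""
    if accession not in matrix.accessions:
        raise ValueError(f"unknown accession {accession!r}")
    col = matrix.calls[accession]
    n_loci = int((col != -1).sum())
    if n_loci == 0:
        raise ValueError(f"no genotyped loci for {accession!r}")
    n_het = int((col == 1).sum())
    l_rad = tag_length * n_loci
    return HeterozygosityRecord(accession, n_het, l_rad, n_het / l_rad * 1000.0)


def rad_genome_size_mb(n_loci: int, tag_length: int = TAG_LENGTH) -> float:
    """Megabases of RAD tag sequence represented by ``n_loci`` tags."""
    return n_loci * tag_length / 1e6


# ---------------------------------------------------------------------------
# within-group diversity and the LOD selection scan


def _pi_from_counts(n0: np.ndarray, nh: np.ndarray, n1: np.ndarray) -> np.ndarray:
    """Mean pairwise 0/0.5/1 genotype distance from genotype counts."""
    m = n0 + nh + n1
    pairs = m * (m - 1) / 2.0
    sums = n0 * n1 * 1.0 + 0.5 * nh * (n0 + n1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(pairs > 0, sums / pairs, np.nan)


def group_pi(
    matrix: GenotypeMatrix,
    group: str | Sequence[str],
    locus: str,
    min_members: int = 3,
) -> float | None:
    """Within-group diversity pi at one locus: the mean pairwise genotype
    distance (0/0.5/1) over all unordered pairs of genotyped members.

    ``group`` is a group label from the matrix or an explicit accession
    list. Returns ``None`` (undefined) when fewer than ``min_members``
    members are genotyped.
    """
    if isinstance(group, str):
        members = matrix.members_of_group(group)
        if not members:
            raise ValueError(f"unknown group {group!r}")
    else:
        members = list(group)
        unknown = set(members) - set(matrix.accessions)
        if unknown:
            raise ValueError(f"unknown accessions {sorted(unknown)}")
    codes = matrix.calls.loc[locus, members].to_numpy()
    codes = codes[codes != -1]
    if len(codes) < min_members:
        return None
    n0 = float((codes == 0).sum())
    nh = float((codes == 1).sum())
    n1 = float((codes == 2).sum())
    return float(_pi_from_counts(np.array(n0), np.array(nh), np.array(n1)))


def _group_pi_vector(
    matrix: GenotypeMatrix, members: Sequence[str], min_members: int
) -> np.ndarray:
    codes = matrix.calls[list(members)].to_numpy()
    n0 = (codes == 0).sum(axis=1).astype(float)
    nh = (codes == 1).sum(axis=1).astype(float)
    n1 = (codes == 2).sum(axis=1).astype(float)
    pi = _pi_from_counts(n0, nh, n1)
    pi[(n0 + nh + n1) < min_members] = np.nan
    return pi


def lod_selection_scan(
    matrix: GenotypeMatrix,
    cultivated: Sequence[str] | None = None,
    wild: Sequence[str] | None = None,
    min_members: int = 3,
) -> pd.DataFrame:
    """Per-locus loss of diversity LOD = 1 - pi_cultivated / pi_wild.

    The selected set is the loci with pi_cultivated == 0 while pi_wild > 0
    (LOD exactly 1): the cultivated group fixed for one allele at a locus
    still polymorphic in the wild. Admixed accessions belong to neither
    group. LOD is undefined (NaN) when pi_wild is 0 or either group has
    fewer than ``min_members`` genotyped members.
    """
    if cultivated is None:
        cultivated = matrix.accessions_in_class("cultivated")
    if wild is None:
        wild = matrix.accessions_in_class("wild")
    cultivated, wild = list(cultivated), list(wild)
    if not cultivated or not wild:
        raise ValueError("both groups must be non-empty")
    overlap = set(cultivated) & set(wild)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    pi_c = _group_pi_vector(matrix, cultivated, min_members)
    pi_w = _group_pi_vector(matrix, wild, min_members)
    with np.errstate(invalid="ignore", divide="ignore"):
        lod = np.where(pi_w > 0, 1.0 - pi_c / pi_w, np.nan)
    lod[np.isnan(pi_c)] = np.nan
    selected = (pi_c == 0) & (pi_w > 0)
    subst = [
        classify_substitution(matrix.ref[l], matrix.alt[l])
        if pd.notna(matrix.ref[l]) and pd.notna(matrix.alt[l])
        else None
        for l in matrix.loci
    ]
    return pd.DataFrame(
        {
            "pi_cultivated": pi_c,
            "pi_wild": pi_w,
            "lod": lod,
            "selected": selected,
            "substitution": subst,
        },
        index=matrix.calls.index,
    )
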