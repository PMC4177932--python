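"""RESL-style OTU ("BIN") clustering and species/OTU concordance.

Specimens are first grouped by single linkage: any pair closer than the
linkage threshold (default 2.2% divergence) joins the same seed OTU.
Because single linkage chains, each seed OTU of three or more members is
then refined by Markov clustering (MCL) on a similarity graph built from
the pairwise distances; refinement only ever subdivides a seed OTU, never
merges two.  The resulting partition is compared against the species
labels with the four-category scheme: *match* (species = one pure OTU),
*split* (species spread over several OTUs, none shared), *merge* (species
confined to one OTU that also holds other species) and *mixture* (both a
split and a merge signal).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix, build_distance_matrix
from .io_formats import Library

logger = logging.getLogger("barcodegap")

CATEGORIES = ("match", "split", "merge", "mixture")


@dataclass
class ClusteringConfig:
    """Parameters of the two-stage clustering.

    linkage_threshold: pairs strictly below this divergence connect in the
        single-linkage stage (default 0.022, i.e. 2.2%).
    divergence_model: 'p' (uncorrected, the RESL convention) or 'K2P'.
    mcl_*: Markov-clustering controls (expansion power, inflation
        exponent, iteration cap, convergence tolerance).
    refine: switch the MCL stage off to get plain single linkage.
    """

    linkage_threshold: float = 0.022
    divergence_model: str = "p"
    mcl_inflation: float = 2.0
    mcl_expansion: int = 2
    mcl_max_iter: int = 100
    mcl_tolerance: float = 1e-6
    refine: bool = True
    min_overlap: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.linkage_threshold < 1.0:
            raise ValueError("linkage_threshold must be in (0, 1)")
        if self.mcl_inflation <= 1.0:
            raise ValueError("mcl_inflation must exceed 1")
        if self.mcl_expansion < 2:
            raise ValueError("mcl_expansion must be >= 2")


@dataclass
class OTUPartition:
    """Specimen -> OTU assignment with stable labels.

    Each OTU is labelled by its lexicographically smallest member
    specimen id, so labels are deterministic for a given partition.
    """

    assignment: dict[str, str]

    @property
    def otu_ids(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    @property
    def n_otus(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, otu in self.assignment.items():
            out.setdefault(otu, []).append(sid)
        return {k: sorted(v) for k, v in out.items()}


def _labels_to_partition(ids: list[str], labels: np.ndarray) -> OTUPartition:
    groups: dict[int, list[str]] = {}
    for sid, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(sid)
    assignment = {}
    for members in groups.values():
        otu_id = min(members)
        for sid in members:
            assignment[sid] = otu_id
    return OTUPartition(assignment=assignment)


def single_linkage_otus(
    matrix: DistanceMatrix, threshold: float = 0.022
) -> OTUPartition:
    """Single-linkage OTUs: connected components of the d < threshold graph.

    Undefined pairs are treated as above-threshold (no edge).
    """
    with np.errstate(invalid="ignore"):
        adj = (matrix.values < threshold) & matrix.defined
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False, connection="weak"
    )
    return _labels_to_partition(matrix.ids, labels)


def markov_cluster(
    weights: np.ndarray,
    expansion: int = 2,
    inflation: float = 2.0,
    max_iter: int = 100,
    tolerance: float = 1e-6,
    prune: float = 1e-12,
) -> tuple[list[list[int]], bool]:
    """Markov clustering of a weighted undirected graph.

    Alternates expansion (matrix power: random-walk flow) and inflation
    (elementwise power then column renormalisation: flow sharpening) until
    the flow matrix changes by less than ``tolerance`` or the iteration
    cap is hit.  Attractors (nodes keeping flow on their diagonal) are
    grouped by the connected components of their mutual support; every
    other node joins the attractor cluster that receives most of its
    flow, ties breaking to the lowest cluster index, so the result is
    always a partition even when a node is attracted by several clusters.
    Returns (clusters as index lists, converged flag).
    """
    n = weights.shape[0]
    M = weights.astype(float).copy()
    colsum = M.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("every node needs positive total weight (add self-loops)")
    M /= colsum
    converged = False
    for _ in range(max_iter):
        new = np.linalg.matrix_power(M, expansion)
        new **= inflation
        new[new < prune] = 0.0
        colsum = new.sum(axis=0)
        colsum[colsum == 0] = 1.0
        new /= colsum
        if np.abs(new - M).max() < tolerance:
            M = new
            converged = True
            break
        M = new
    eps = 1e-8
    attractors = np.flatnonzero(np.diag(M) > eps)
    if attractors.size == 0:
        return [list(range(n))], converged
    sub = M[np.ix_(attractors, attractors)]
    support = (sub > eps) | (sub.T > eps)
    n_comp, labels = connected_components(
        csr_matrix(support), directed=False, connection="weak"
    )
    clusters: list[list[int]] = [[] for _ in range(n_comp)]
    for a, lab in zip(attractors, labels):
        clusters[lab].append(int(a))
    attractor_set = set(int(a) for a in attractors)
    for node in range(n):
        if node in attractor_set:
            continue
        # flow from node's column into each attractor cluster
        mass = [M[np.array(c), node].sum() for c in clusters]
        clusters[int(np.argmax(mass))].append(node)
    return [sorted(c) for c in clusters if c], converged


def similarity_weights(sub: np.ndarray, threshold: float) -> np.ndarray:
    """Similarity graph for MCL: w = max(0, 1 - d/threshold), self-loops 1.

    Monotone in similarity, zero at and beyond the linkage threshold,
    bounded in [0, 1]; undefined distances contribute no edge.
    """
    with np.errstate(invalid="ignore"):
        w = 1.0 - sub / threshold
    w = np.where(np.isnan(w), 0.0, np.clip(w, 0.0, 1.0))
    np.fill_diagonal(w, 1.0)
    return w


def mcl_refine(
    partition: OTUPartition,
    matrix: DistanceMatrix,
    config: Optional[ClusteringConfig] = None,
) -> OTUPartition:
    """Refine a single-linkage partition by Markov clustering.

    Each seed OTU with at least three members is re-clustered on its
    internal similarity graph; when MCL finds more than one cluster the
    seed OTU is replaced by the subclusters (relabelled by smallest
    member).  Seed OTUs are never merged.  Non-convergent MCL leaves the
    seed OTU intact with a warning.
    """
    if config is None:
        config = ClusteringConfig()
    if not config.refine:
        return OTUPartition(assignment=dict(partition.assignment))

    assignment = dict(partition.assignment)
    for otu_id, members in partition.members().items():
        if len(members) < 3:
            continue
        sub = matrix.submatrix(members)
        w = similarity_weights(sub.values, config.linkage_threshold)
        clusters, converged = markov_cluster(
            w,
            expansion=config.mcl_expansion,
            inflation=config.mcl_inflation,
            max_iter=config.mcl_max_iter,
            tolerance=config.mcl_tolerance,
        )
        if not converged:
            msg = f"MCL did not converge for OTU {otu_id!r}; left unsplit"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        if len(clusters) <= 1:
            continue
        for idx_list in clusters:
            names = [members[i] for i in idx_list]
            label = min(names)
            for sid in names:
                assignment[sid] = label
    return OTUPartition(assignment=assignment)


def assign_bins(
    library: Library, config: Optional[ClusteringConfig] = None
) -> OTUPartition:
    """Full OTU pipeline: distances -> single linkage -> MCL refinement."""
    if config is None:
        config = ClusteringConfig()
    matrix = build_distance_matrix(
        library, model=config.divergence_model, min_overlap=config.min_overlap
    )
    seeds = single_linkage_otus(matrix, config.linkage_threshold)
    return mcl_refine(seeds, matrix, config)


@dataclass
class ConcordanceReport:
    """Species/OTU concordance under the four-category scheme."""

    category_of: dict[str, str]
    counts: dict[str, int] = field(init=False)
    percentages: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.counts = {c: 0 for c in CATEGORIES}
        for cat in self.category_of.values():
            self.counts[cat] += 1
        total = len(self.category_of)
        self.percentages = {
            c: (100.0 * self.counts[c] / total if total else 0.0)
            for c in CATEGORIES
        }

    @property
    def n_species(self) -> int:
        return len(self.category_of)

    def species_in(self, category: str) -> list[str]:
        return sorted(sp for sp, c in self.category_of.items() if c == category)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": sp, "category": cat}
            for sp, cat in sorted(self.category_of.items())
        )


def concordance_classify(
    partition: OTUPartition, library: Library
) -> ConcordanceReport:
    """Classify every species as match / split / merge / mixture.

    A species has a *split signal* when its specimens span two or more
    OTUs and a *merge signal* when any of its OTUs also contains another
    species.  Match = neither signal; split = split only; merge = merge
    only; mixture = both.
    """
    unlabeled = [r.specimen_id for r in library if not r.species]
    if unlabeled:
        raise ValueError(f"specimens without species label: {unlabeled[:5]}")
    missing = [r.specimen_id for r in library
               if r.specimen_id not in partition.assignment]
    if missing:
        raise ValueError(f"specimens without OTU assignment: {missing[:5]}")

    otus_of_species: dict[str, set[str]] = {}
    species_of_otu: dict[str, set[str]] = {}
    for r in library:
        otu = partition.assignment[r.specimen_id]
        otus_of_species.setdefault(r.species, set()).add(otu)
        species_of_otu.setdefault(otu, set()).add(r.species)

    category_of = {}
    for sp, otus in otus_of_species.items():
        split_signal = len(otus) > 1
        merge_signal = any(len(species_of_otu[o]) > 1 for o in otus)
        if split_signal and merge_signal:
            category_of[sp] = "mixture"
        elif split_signal:
            category_of[sp] = "split"
        elif merge_signal:
            category_of[sp] = "merge"
        else:
            category_of[sp] = "match"
    return ConcordanceReport(category_of=category_of)


def partition_to_frame(partition: OTUPartition, library: Library) -> pd.DataFrame:
    """Specimen/species/OTU table (TSV-ready)."""
    return pd.DataFrame(
        {
            "specimen_id": r.specimen_id,
            "species": r.species,
            "otu_id": partition.assignment[r.specimen_id],
        }
        for r in library
    )
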