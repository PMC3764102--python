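"""Expression-module-to-trait network and candidate-gene intersection.

Gene nitrogen-response profiles (per-accession log2 control-minus-treated
responses) are clustered with average linkage on 1 - Pearson and the tree
cut at correlation R = 0.7 (distance 0.3).  A randomisation null —
independently permuting each gene's profile across accessions — calibrates
the minimum size at which a cluster is unlikely to arise by chance, and
clusters at or above that size are "major".  Major-cluster centroids are
correlated against scaled trait responses across the same accessions, an
absolute correlation above 0.7 defining a network edge.  Candidate genes
are the genes inside SNP groups associated with a target trait, tiered by
expression evidence (any ANOVA effect; membership of the stringent set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .gwas import SnpGroup
from .traits import correlation_distance_matrix

DEFAULT_EDGE_R = 0.7
DEFAULT_NULL_PERCENTILE = 0.10


def _cut_at_distance(profiles: pd.DataFrame, cut_r: float) -> pd.Series:
    D = correlation_distance_matrix(profiles.to_numpy())
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=1.0 - cut_r, criterion="distance")
    return pd.Series(labels, index=profiles.index, name="cluster")


@dataclass
class MajorClusters:
    labels: pd.Series  # cluster id per gene (all clusters)
    members: dict[int, list[str]]  # major clusters only
    centroids: pd.DataFrame  # major cluster id x accession mean response
    size_threshold: int
    null_max_sizes: np.ndarray


def major_clusters(
    profiles: pd.DataFrame,
    cut_r: float = DEFAULT_EDGE_R,
    null_percentile: float = DEFAULT_NULL_PERCENTILE,
    n_randomizations: int = 100,
    seed: int = 0,
) -> MajorClusters:
    """Find response-profile clusters larger than chance expects.

    The size threshold is the smallest cluster size whose exceedance
    frequency — the fraction of randomised datasets whose largest cluster
    reaches that size — falls below ``null_percentile``.  Randomisation
    permutes each gene's profile independently across accessions,
    destroying inter-gene correlation while preserving marginals.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two genes")
    if profiles.isna().any().any():
        raise ValueError("profiles must be complete")
    if n_randomizations < 20:
        raise ValueError("n_randomizations < 20 makes the threshold unstable")
    rng = np.random.default_rng(seed)
    labels = _cut_at_distance(profiles, cut_r)

    X = profiles.to_numpy()
    max_sizes = np.empty(n_randomizations, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_randomizations):
            perm = rng.permuted(X, axis=1)
            rl = _cut_at_distance(pd.DataFrame(perm, index=profiles.index), cut_r)
            max_sizes[b] = int(rl.value_counts().iloc[0])
    sizes = labels.value_counts()
    threshold = None
    for s in range(2, int(sizes.iloc[0]) + 1):
        if np.mean(max_sizes >= s) < null_percentile:
            threshold = s
            break
    if threshold is None:
        threshold = int(max_sizes.max()) + 1
    members = {
        int(cid): sorted(labels.index[labels == cid])
        for cid, size in sizes.items()
        if size >= threshold
    }
    centroids = pd.DataFrame(
        {cid: profiles.loc[genes].mean(axis=0) for cid, genes in members.items()}
    ).T
    centroids.index.name = "cluster"
    return MajorClusters(
        labels=labels,
        members=members,
        centroids=centroids,
        size_threshold=threshold,
        null_max_sizes=max_sizes,
    )


@dataclass
class ModuleTraitNetwork:
    graph: nx.Graph
    correlations: pd.DataFrame  # clusters x traits, full R matrix
    edges: pd.DataFrame  # cluster, trait, R, sign
    edge_r: float


def module_trait_network(
    clusters: MajorClusters,
    trait_matrix: pd.DataFrame,
    edge_r: float = DEFAULT_EDGE_R,
) -> ModuleTraitNetwork:
    """Correlate major-cluster centroids with traits across accessions.

    ``trait_matrix`` is accessions x traits (e.g. scaled trait responses
    delta highN-lowN); an edge joins a cluster and a trait iff |R| >
    ``edge_r``.  Zero-variance centroids or traits yield no edges, with a
    warning.
    """
    cent = clusters.centroids
    accs = cent.columns.intersection(trait_matrix.index)
    if len(accs) < 3:
        raise ValueError("need >= 3 shared accessions")
    C = cent[accs].to_numpy(dtype=float)
    T = trait_matrix.loc[accs].to_numpy(dtype=float)
    csd, tsd = C.std(axis=1), T.std(axis=0)
    if (csd == 0).any() or (tsd == 0).any():
        warnings.warn("zero-variance centroid or trait: no edges for it")
    Cz = (C - C.mean(axis=1, keepdims=True))
    Tz = (T - T.mean(axis=0, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Cz @ Tz) / (len(accs) * np.outer(csd, tsd))
    corr = pd.DataFrame(R, index=cent.index, columns=trait_matrix.columns)
    g = nx.Graph()
    for cid in cent.index:
        g.add_node(f"cluster:{cid}", kind="cluster", size=len(clusters.members[cid]))
    for t in trait_matrix.columns:
        g.add_node(f"trait:{t}", kind="trait")
    rows = []
    for cid in corr.index:
        for t in corr.columns:
            r = corr.loc[cid, t]
            if np.isfinite(r) and abs(r) > edge_r:
                g.add_edge(f"cluster:{cid}", f"trait:{t}", r=float(r))
                rows.append({"cluster": cid, "trait": t, "R": float(r),
                             "sign": "+" if r > 0 else "-"})
    edges = pd.DataFrame(rows, columns=["cluster", "trait", "R", "sign"])
    return ModuleTraitNetwork(graph=g, correlations=corr, edges=edges, edge_r=edge_r)


def stringent_set(
    classes: pd.Series,
    clusters: MajorClusters,
    correlations: pd.DataFrame,
    target_trait_prefix: str = "LRlengthave",
    edge_r: float = DEFAULT_EDGE_R,
) -> set[str]:
    """Union of interaction genes and genes in target-trait-correlated clusters.

    Takes every gene classed NxAccession plus every gene belonging to a
    major cluster whose centroid correlates (|R| > ``edge_r``) with any
    trait column whose name starts with ``target_trait_prefix`` (the lowN,
    highN and delta versions of the trait).
    """
    genes = set(classes.index[classes == "NxAccession"])
    trait_cols = [c for c in correlations.columns if str(c).startswith(target_trait_prefix)]
    for cid in correlations.index:
        if any(
            np.isfinite(correlations.loc[cid, t]) and abs(correlations.loc[cid, t]) > edge_r
            for t in trait_cols
        ):
            genes.update(clusters.members.get(int(cid), []))
    return genes


def candidate_genes(
    snp_groups: list[SnpGroup],
    classes: pd.Series,
    stringent: set[str],
    target_trait: str = "LRlengthave",
) -> pd.DataFrame:
    """Rank genes in SNP groups associated with the target trait.

    Tier "a" genes show any significant ANOVA effect (class other than
    none); the stringent flag marks membership of the stringent set.
    Sorted by stringent membership, then tier, then absolute SNP distance.
    Returns an empty frame when no group carries the target trait.
    """
    rows = []
    for grp in snp_groups:
        if not any(str(t).startswith(target_trait) for t in grp.traits):
            continue
        for gene, dist in grp.genes:
            cls = classes.get(gene, "none")
            rows.append(
                {
                    "gene_id": gene,
                    "group_id": grp.group_id,
                    "chrom": grp.chrom,
                    "traits": ";".join(sorted(str(t) for t in grp.traits)),
                    "distance": dist,
                    "anova_class": cls,
                    "has_anova_effect": cls != "none",
                    "stringent": gene in stringent,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "group_id", "chrom", "traits", "distance",
                 "anova_class", "has_anova_effect", "stringent"],
    )
    if df.empty:
        return df
    df = df.sort_values(
        by=["stringent", "has_anova_effect", "distance"],
        key=lambda s: s.abs() if s.name == "distance" else ~s,
    ).reset_index(drop=True)
    return df
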