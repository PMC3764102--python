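import numpy as np
import pandas as pd
import pytest

from rootplast import gwas, synthetic


@pytest.fixture(scope="session")
def small_panel():
    """Unstructured 30-accession, 200-SNP panel."""
    gm, truth = synthetic.simulate_genotypes(30, 200, seed=11)
    return gm, truth


@pytest.fixture(scope="session")
def structured_panel():
    """Two-subpopulation panel with strong divergence."""
    gm, truth = synthetic.simulate_genotypes(60, 800, n_subpops=2, divergence=0.3, seed=7)
    return gm, truth


@pytest.fixture(scope="session")
def small_kinship(small_panel):
    gm, _ = small_panel
    return gwas.compute_kinship(gm)


@pytest.fixture(scope="session")
def expression_cube():
    """Clean 400-gene expression study (no planted attenuation)."""
    return synthetic.simulate_expression_study(400, seed=21)


@pytest.fixture(scope="session")
def trait_study(small_panel):
    gm, _ = small_panel
    measurements, table, truth = synthetic.simulate_root_traits(
        gm, n_replicates=6, seed=13
    )
    return measurements, table, truth


def brute_force_average_linkage(D: np.ndarray):
    """O(n^3) average-linkage oracle: returns the merge sequence.

    Each merge is (member set A, member set B, distance); cluster distances
    are recomputed from scratch as the mean of all inter-cluster pairwise
    distances at every step.
    """
    clusters = [frozenset([i]) for i in range(len(D))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def union_find_groups(intervals):
    """Brute-force transitive closure of interval overlap (per chromosome).

    ``intervals``: list of (chrom, start, end).  Returns a list of
    frozensets of indices.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci == cj and si <= ej and sj <= ei:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(v) for v in groups.values()]
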