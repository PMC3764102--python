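"""Kinship-corrected genome-wide association and power analysis.

The scan fits, per SNP, a mixed model with an identity-by-state kinship
random effect (REML variance ratio re-estimated per marker, EMMA style),
controls the per-trait false discovery rate with Storey q-values, and
collapses significant SNPs into 20 kb windows merged into groups wherever
windows overlap.  The power analysis follows the allele-reassignment
scheme: empirical phenotypes are treated as random deviates, a simulated
biallelic genotype at a chosen minor allele frequency is assigned at
random, an additive effect proportional to the phenotypic standard
deviation is added to one allele class, and the structured association test
is run against the real kinship matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import fit_reml

DEFAULT_MAF_THRESHOLD = 0.1
DEFAULT_WINDOW_HALF_WIDTH = 10_000
DEFAULT_EFFECT_MULTIPLIERS = (0.1, 0.2, 0.5, 0.7, 0.9, 1.0)


@dataclass
class GenotypeMatrix:
    """Biallelic inbred SNP calls, coded 0/1 with NaN for missing.

    ``snps`` is indexed by SNP id with columns chrom and pos (1-based);
    ``calls`` shares that index with one column per accession.  Positions
    must be strictly increasing within each chromosome.
    """

    snps: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.snps.index.equals(self.calls.index):
            raise ValueError("snps and calls must share an index")
        for _, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing per chromosome")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            raise ValueError("calls must be 0, 1 or missing")

    @property
    def accessions(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_snps(self) -> int:
        return len(self.snps)


def compute_maf(genotypes: GenotypeMatrix) -> pd.Series:
    """Minor allele frequency per SNP over non-missing calls."""
    freq = genotypes.calls.mean(axis=1, skipna=True)
    return pd.Series(np.minimum(freq, 1.0 - freq), index=genotypes.snps.index, name="maf")


def filter_maf(
    genotypes: GenotypeMatrix, threshold: float = DEFAULT_MAF_THRESHOLD
) -> GenotypeMatrix:
    """Keep SNPs with MAF >= threshold; all-missing SNPs are dropped."""
    all_missing = genotypes.calls.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} SNPs with no calls")
    maf = compute_maf(genotypes)
    keep = (~all_missing) & (maf >= threshold)
    return GenotypeMatrix(snps=genotypes.snps.loc[keep], calls=genotypes.calls.loc[keep])


def compute_kinship(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Identity-by-state kinship: pairwise allele-sharing fraction.

    For each pair of accessions the fraction of SNPs, non-missing in both,
    at which the calls agree.  Entries lie in [0, 1] with unit diagonal.
    """
    X = genotypes.calls.to_numpy(dtype=float).T  # accessions x snps
    if X.shape[0] < 2:
        raise ValueError("need at least two accessions")
    obs = ~np.isnan(X)
    A = np.where(obs, X, 0.0)
    B = np.where(obs, 1.0 - X, 0.0)
    agree = A @ A.T + B @ B.T
    valid = obs.astype(float) @ obs.astype(float).T
    if (valid == 0).any():
        raise ValueError("some accession pair shares no non-missing SNPs")
    K = agree / valid
    np.fill_diagonal(K, 1.0)
    acc = genotypes.accessions
    return pd.DataFrame(0.5 * (K + K.T), index=acc, columns=acc)


def snp_r2(trait: np.ndarray, calls: np.ndarray) -> float:
    """One-way fixed-effect ANOVA R^2 of the trait on the SNP genotype.

    R^2 = SS(model) / SS(total), i.e. the between-genotype-class sum of
    squares over the total.  Requires both genotype classes present.
    """
    y = np.asarray(trait, dtype=float)
    g = np.asarray(calls, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(g))
    y, g = y[ok], g[ok]
    classes = np.unique(g)
    if len(classes) < 2:
        raise ValueError("SNP is monomorphic in the phenotyped accessions")
    grand = y.mean()
    ss_tot = float(np.sum((y - grand) ** 2))
    if ss_tot == 0:
        return 0.0
    ss_mod = 0.0
    for c in classes:
        yc = y[g == c]
        ss_mod += len(yc) * (yc.mean() - grand) ** 2
    return float(ss_mod / ss_tot)


def mixed_model_scan(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    K: pd.DataFrame,
    *,
    per_snp_reml: bool = True,
    with_r2: bool = True,
) -> pd.DataFrame:
    """Association scan of one trait against every SNP.

    For each SNP the model y = mu + b.g + u + e with cov(u) = sg2*K is fit
    by REML on the accessions with non-missing calls (complete-case per
    SNP) and the SNP coefficient is Wald-tested.  With ``per_snp_reml``
    False the variance ratio is estimated once under the null model and
    reused (an EMMAX-style approximation).  Returns a frame indexed by SNP
    id with columns chrom, pos, maf, effect, p and (optionally) r2.
    """
    acc = genotypes.accessions
    y_full = trait.reindex(acc).to_numpy(dtype=float)
    if np.isnan(y_full).any():
        raise ValueError("trait missing for some genotyped accessions")
    if np.std(y_full) == 0:
        raise ValueError("trait is constant")
    Km = K.reindex(index=acc, columns=acc).to_numpy(dtype=float)
    if np.isnan(Km).any():
        raise ValueError("kinship missing for some accessions")
    eigmin = np.linalg.eigvalsh(Km).min()
    if eigmin < -1e-6:
        raise ValueError("kinship matrix is not positive semidefinite")

    shared_delta = None
    if not per_snp_reml:
        null = fit_reml(y_full, np.ones((len(acc), 1)), Km)
        shared_delta = null.delta

    G = genotypes.calls.to_numpy(dtype=float)
    rows = []
    for i, snp in enumerate(genotypes.snps.index):
        g = G[i]
        ok = ~np.isnan(g)
        y, gv = y_full[ok], g[ok]
        freq = gv.mean()
        maf = min(freq, 1.0 - freq)
        if len(np.unique(gv)) < 2:
            rows.append((np.nan, np.nan, maf, np.nan))
            continue
        X = np.column_stack([np.ones(ok.sum()), gv])
        Ks = Km[np.ix_(ok, ok)]
        fit = fit_reml(y, X, Ks, delta=shared_delta)
        r2 = snp_r2(y, gv) if with_r2 else np.nan
        rows.append((fit.beta[1], fit.p_wald[1], maf, r2))
    out = pd.DataFrame(
        rows, index=genotypes.snps.index, columns=["effect", "p", "maf", "r2"]
    )
    out.insert(0, "pos", genotypes.snps["pos"].to_numpy())
    out.insert(0, "chrom", genotypes.snps["chrom"].to_numpy())
    return out


def ols_scan(trait: pd.Series, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Naive (structure-unaware) per-SNP OLS F-test scan, for comparison."""
    acc = genotypes.accessions
    y_full = trait.reindex(acc).to_numpy(dtype=float)
    G = genotypes.calls.to_numpy(dtype=float)
    rows = []
    for i in range(G.shape[0]):
        g = G[i]
        ok = ~np.isnan(g)
        y, gv = y_full[ok], g[ok]
        if len(np.unique(gv)) < 2 or np.std(y) == 0:
            rows.append((np.nan, np.nan))
            continue
        res = stats.linregress(gv, y)
        rows.append((res.slope, res.pvalue))
    return pd.DataFrame(rows, index=genotypes.snps.index, columns=["effect", "p"])


def storey_pi0(p: np.ndarray, lambda_grid: np.ndarray | None = None) -> float:
    """Storey smoother estimate of the null proportion pi0.

    pi0 is estimated at each lambda in {0, 0.05, ..., 0.90}, a cubic
    polynomial is fit to the sequence and evaluated at the largest lambda,
    and the result clipped to (0, 1].  With fewer than 100 p-values the
    smoother is unstable and pi0 = 1 is returned.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m < 100:
        return 1.0
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 0.9001, 0.05)
    pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambda_grid])
    coeffs = np.polyfit(lambda_grid, pi0_lam, 3)
    pi0 = float(np.polyval(coeffs, lambda_grid.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(p: np.ndarray, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values for one trait's p-values.

    q_i = min over p_(j) >= p_(i) of pi0 * m * p_(j) / rank(j); with pi0
    forced to 1 this is exactly the Benjamini-Hochberg step-up adjustment.
    Returns (q, pi0) with q in the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0 is None:
        pi0 = storey_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, float(pi0)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid gene interval {self.gene_id}")


@dataclass
class SnpWindow:
    """20 kb interval centred on a significant SNP with overlapping genes."""

    snp_id: str
    chrom: str
    pos: int
    start: int
    end: int
    genes: list[tuple[str, int]] = field(default_factory=list)  # (gene, signed dist)
    traits: set[str] = field(default_factory=set)


@dataclass
class SnpGroup:
    group_id: str
    chrom: str
    start: int
    end: int
    snp_ids: list[str]
    genes: list[tuple[str, int]]
    traits: set[str]


def _signed_distance(pos: int, gene: GeneModel) -> int:
    """Distance from SNP to the nearest gene boundary.

    Zero when the SNP lies inside the gene; positive when the gene is
    downstream (to the right) of the SNP; negative when upstream.
    """
    if gene.start <= pos <= gene.end:
        return 0
    if pos < gene.start:
        return gene.start - pos
    return gene.end - pos


def assign_windows(
    significant: pd.DataFrame,
    genes: list[GeneModel],
    half_width: int = DEFAULT_WINDOW_HALF_WIDTH,
    trait_label: str | None = None,
) -> list[SnpWindow]:
    """Build a clipped [pos - hw, pos + hw] window around each SNP.

    ``significant`` must carry columns chrom and pos indexed by SNP id.  A
    gene is a member iff its interval overlaps the window at all (1-based
    inclusive, strand-agnostic).  SNPs on chromosomes absent from the
    annotation yield empty windows with a warning.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for gm in genes:
        by_chrom.setdefault(str(gm.chrom), []).append(gm)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start, g.end))
    windows = []
    for snp_id, row in significant.iterrows():
        chrom, pos = str(row["chrom"]), int(row["pos"])
        start = max(pos - half_width, 1)
        end = pos + half_width
        members = []
        if chrom not in by_chrom:
            warnings.warn(f"SNP {snp_id}: chromosome {chrom} absent from annotation")
        else:
            for gm in by_chrom[chrom]:
                if gm.start <= end and gm.end >= start:
                    members.append((gm.gene_id, _signed_distance(pos, gm)))
        labels = {trait_label} if trait_label else set()
        if "trait" in row.index and pd.notna(row.get("trait")):
            labels.add(str(row["trait"]))
        windows.append(
            SnpWindow(str(snp_id), chrom, pos, start, end, members, labels)
        )
    return windows


def merge_groups(windows: list[SnpWindow], per_trait: bool = False) -> list[SnpGroup]:
    """Merge overlapping windows into SNP groups (transitive closure).

    With ``per_trait`` True, windows are only merged when they share a
    trait label family; the default merges across traits, pooling labels.
    """
    def keyfun(w: SnpWindow):
        if per_trait:
            return (w.chrom, tuple(sorted(w.traits)) or ("",))
        return (w.chrom,)

    buckets: dict[tuple, list[SnpWindow]] = {}
    for w in windows:
        buckets.setdefault(keyfun(w), []).append(w)
    groups: list[SnpGroup] = []
    for _, ws in sorted(buckets.items(), key=lambda kv: kv[0]):
        ws = sorted(ws, key=lambda w: (w.start, w.end))
        current: list[SnpWindow] = []
        cur_end = None
        def flush():
            if not current:
                return
            genes: dict[str, int] = {}
            for w in current:
                for gid, d in w.genes:
                    if gid not in genes or abs(d) < abs(genes[gid]):
                        genes[gid] = d
            groups.append(
                SnpGroup(
                    group_id=f"grp{len(groups) + 1}",
                    chrom=current[0].chrom,
                    start=min(w.start for w in current),
                    end=max(w.end for w in current),
                    snp_ids=[w.snp_id for w in current],
                    genes=sorted(genes.items(), key=lambda kv: abs(kv[1])),
                    traits=set().union(*(w.traits for w in current)),
                )
            )
        for w in ws:
            if cur_end is None or w.start > cur_end:
                flush()
                current = [w]
                cur_end = w.end
            else:
                current.append(w)
                cur_end = max(cur_end, w.end)
        flush()
    return groups


def power_simulation(
    trait: pd.Series,
    K: pd.DataFrame,
    maf_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
    effect_multipliers: tuple[float, ...] = DEFAULT_EFFECT_MULTIPLIERS,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Allele-reassignment power simulation for structured association.

    Per (MAF, multiplier) cell and replicate: x = round(MAF * n)
    accessions are randomly assigned the minor simulated allele, an
    additive effect of multiplier times the phenotypic standard deviation
    is added to their empirical phenotypes, and the mixed-model test is run
    with the real kinship matrix.  Power is the fraction of replicates with
    p < alpha.  Returns a frame with columns maf, multiplier, power, reps.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not effect_multipliers:
        raise ValueError("empty effect grid")
    acc = list(trait.index)
    y0 = trait.to_numpy(dtype=float)
    n = len(y0)
    Km = K.reindex(index=acc, columns=acc).to_numpy(dtype=float)
    sd = float(np.std(y0, ddof=1))
    rng = np.random.default_rng(seed)
    rows = []
    for maf in maf_grid:
        x = int(round(maf * n))
        if x < 1:
            raise ValueError(f"MAF {maf} gives no minor-allele accessions at n={n}")
        assignments = [rng.permutation(n)[:x] for _ in range(reps)]
        for mult in effect_multipliers:
            effect = mult * sd
            hits = 0
            for idx in assignments:
                g = np.zeros(n)
                g[idx] = 1.0
                y = y0 + effect * g
                X = np.column_stack([np.ones(n), g])
                fit = fit_reml(y, X, Km)
                if fit.p_wald[1] < alpha:
                    hits += 1
            rows.append({"maf": maf, "multiplier": mult, "power": hits / reps, "reps": reps})
    return pd.DataFrame(rows)
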