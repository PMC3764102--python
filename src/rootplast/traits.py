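"""Root-architecture trait derivation, clustering, ANOVA and heritability.

Seven traits are derived from per-seedling root measurements: primary root
length (PR), lateral root count (LR#), lateral root density (LR# per cm of
PR), the branching-zone fraction (L_B/PR), total lateral root length
(LRtot), total root length (PR+LRtot) and average lateral root length
(LRlengthave).  Accessions are clustered on 0-1 scaled trait values with
average linkage on a 1 - Pearson distance, with the tree cut at the cluster
count maximising the mean silhouette width.  Genotype-by-environment
structure is quantified with a balanced two-way mixed ANOVA and with REML
variance-component heritabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

TRAIT_NAMES = [
    "PR",
    "LR_count",
    "LRdensity",
    "LB_over_PR",
    "LRtot",
    "PR_LRtot",
    "LRlengthave",
]

ENVIRONMENTS = ("lowN", "highN")


@dataclass
class RootMeasurement:
    """One seedling's root measurements in one environment.

    ``lr_lengths`` lists the lengths (cm) of all emerged lateral roots;
    ``branching_zone`` is the parent-root span from the shoot base to the
    most rootward emerged lateral root (cm) and must not exceed ``pr``.
    """

    accession: str
    environment: str
    replicate: int
    pr: float
    lr_lengths: list[float] = field(default_factory=list)
    branching_zone: float = 0.0
    shoot_area: float | None = None

    def validate(self) -> None:
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.pr < 0 or self.branching_zone < 0 or any(l < 0 for l in self.lr_lengths):
            raise ValueError("lengths must be non-negative")
        if self.branching_zone > self.pr + 1e-9:
            raise ValueError("branching zone longer than primary root")
        if self.pr == 0 and self.lr_lengths:
            raise ValueError("lateral roots recorded on a zero-length primary root")


@dataclass
class TraitTable:
    """Replicate-level trait vectors plus per (accession, environment) summary.

    ``replicates`` has columns accession, environment, replicate and the
    seven traits; ``means``/``se``/``n`` are indexed by (accession,
    environment).  Standard errors are only defined for n >= 2.
    """

    replicates: pd.DataFrame
    means: pd.DataFrame
    se: pd.DataFrame
    n: pd.Series


def derive_traits(measurements: list[RootMeasurement]) -> TraitTable:
    """Compute the seven root traits per replicate and summarise.

    LRlengthave is missing (NaN) when a seedling has no lateral roots;
    LRdensity and L_B/PR are missing when PR is zero.
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    rows = []
    for m in measurements:
        m.validate()
        lr_count = len(m.lr_lengths)
        lrtot = float(sum(m.lr_lengths))
        rows.append(
            {
                "accession": m.accession,
                "environment": m.environment,
                "replicate": m.replicate,
                "PR": m.pr,
                "LR_count": lr_count,
                "LRdensity": lr_count / m.pr if m.pr > 0 else np.nan,
                "LB_over_PR": m.branching_zone / m.pr if m.pr > 0 else np.nan,
                "LRtot": lrtot,
                "PR_LRtot": m.pr + lrtot,
                "LRlengthave": lrtot / lr_count if lr_count > 0 else np.nan,
            }
        )
    reps = pd.DataFrame(rows)
    grouped = reps.groupby(["accession", "environment"])[TRAIT_NAMES]
    means = grouped.mean()
    n = grouped.size().rename("n")
    sd = grouped.std(ddof=1)
    se = sd.div(np.sqrt(n), axis=0)
    se[n < 2] = np.nan
    return TraitTable(replicates=reps, means=means, se=se, n=n)


@dataclass
class ScaledTraitMatrix:
    """Column-wise 0-1 scaled matrix with the anchors used per column."""

    values: pd.DataFrame
    anchors: pd.DataFrame  # columns: low, high
    missing_policy: str


def scale_traits(table: pd.DataFrame, missing_policy: str = "zero") -> ScaledTraitMatrix:
    """Scale each column to [0, 1] via (x - low) / (high - low).

    Missing values are excluded from the anchors and then filled according
    to ``missing_policy``: "zero" sets them to 0 on the scaled scale (the
    convention used for clustering input), "keep" leaves them missing.
    Constant columns are emitted as all-zero with a warning.
    """
    if missing_policy not in ("zero", "keep"):
        raise ValueError("missing_policy must be 'zero' or 'keep'")
    df = pd.DataFrame(table).astype(float)
    lows = df.min(axis=0)
    highs = df.max(axis=0)
    if df.notna().sum(axis=0).min() < 1:
        raise ValueError("a column has no non-missing values")
    scaled = {}
    for col in df.columns:
        lo, hi = lows[col], highs[col]
        if hi == lo:
            warnings.warn(f"constant column {col!r}: emitted as all zeros")
            scaled[col] = pd.Series(0.0, index=df.index).where(df[col].notna())
        else:
            scaled[col] = (df[col] - lo) / (hi - lo)
    out = pd.DataFrame(scaled, index=df.index)
    if missing_policy == "zero":
        out = out.fillna(0.0)
    anchors = pd.DataFrame({"low": lows, "high": highs})
    return ScaledTraitMatrix(values=out, anchors=anchors, missing_policy=missing_policy)


def trait_deltas(table: TraitTable) -> pd.DataFrame:
    """Per-accession trait difference highN minus lowN.

    Accessions missing either environment are excluded with a warning.
    """
    means = table.means
    by_env = {env: means.xs(env, level="environment") for env in ENVIRONMENTS}
    common = by_env["lowN"].index.intersection(by_env["highN"].index)
    dropped = set(means.index.get_level_values("accession")) - set(common)
    if dropped:
        warnings.warn(f"accessions missing one environment excluded: {sorted(dropped)}")
    return by_env["highN"].loc[common] - by_env["lowN"].loc[common]


def correlation_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson distances between rows.

    Rows with zero variance have undefined correlations; by convention they
    are assigned distance 1 to every other row (and 0 to themselves /
    exact duplicates), with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance rows: distance set to 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    D = 1.0 - R
    D[np.isnan(D)] = 1.0
    for i in np.flatnonzero(degenerate):
        same = np.all(X == X[i], axis=1)
        D[i, :] = 1.0
        D[:, i] = 1.0
        D[i, same] = 0.0
        D[same, i] = 0.0
    np.fill_diagonal(D, 0.0)
    return np.clip(0.5 * (D + D.T), 0.0, None)


@dataclass
class DendrogramPartition:
    """Average-linkage tree with the silhouette-selected flat partition."""

    linkage: np.ndarray
    labels: pd.Series  # cluster id per row
    silhouettes: pd.Series
    n_clusters: int
    mean_silhouette: float


def cluster_rows(matrix: pd.DataFrame, k_max: int = 15) -> DendrogramPartition:
    """Cluster rows by average linkage on 1 - Pearson distance.

    Candidate cluster counts k = 2 .. min(k_max, n - 1) are cut from the
    tree and the k maximising the mean silhouette width is chosen, ties
    resolved toward smaller k.
    """
    df = pd.DataFrame(matrix)
    n, p = df.shape
    if n < 3 or p < 2:
        raise ValueError("need at least 3 rows and 2 columns")
    D = correlation_distance_matrix(df.to_numpy())
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    best = None
    for k in range(2, min(k_max, n - 1) + 1):
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_samples(D, labels, metric="precomputed")
        score = float(np.mean(sil))
        if best is None or score > best[0] + 1e-12:
            best = (score, k, labels, sil)
    if best is None:  # all rows identical: a single cluster
        labels = np.ones(n, dtype=int)
        return DendrogramPartition(Z, pd.Series(labels, index=df.index),
                                   pd.Series(np.zeros(n), index=df.index), 1, 0.0)
    score, k, labels, sil = best
    return DendrogramPartition(
        linkage=Z,
        labels=pd.Series(labels, index=df.index),
        silhouettes=pd.Series(sil, index=df.index),
        n_clusters=int(k),
        mean_silhouette=score,
    )


@dataclass
class PcaResult:
    loadings: pd.DataFrame  # traits x components, orthonormal columns
    scores: pd.DataFrame  # rows x components
    percent_variance: pd.Series


def pca(matrix: pd.DataFrame) -> PcaResult:
    """Principal components of a rows-by-traits matrix.

    Columns are centred but not re-standardised (the inputs are already 0-1
    scaled); components are ordered by explained variance and the percent
    variances over all retained components sum to 100.
    """
    df = pd.DataFrame(matrix).astype(float)
    X = df.to_numpy()
    if X.shape[0] < 2:
        raise ValueError("need at least two rows")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("matrix is constant: PCA undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ncomp = int(np.sum(s > s[0] * 1e-12))
    s = s[:ncomp]
    var = s**2
    comps = [f"PC{i + 1}" for i in range(ncomp)]
    return PcaResult(
        loadings=pd.DataFrame(Vt[:ncomp].T, index=df.columns, columns=comps),
        scores=pd.DataFrame(U[:, :ncomp] * s, index=df.index, columns=comps),
        percent_variance=pd.Series(100.0 * var / var.sum(), index=comps),
    )


@dataclass
class GxeAnovaResult:
    """Balanced two-way mixed ANOVA (environment fixed, genotype random)."""

    anova: pd.DataFrame  # index ENV/GEN/GENxENV/ERROR: ss, df, ms, F, p
    interaction_coefficients: pd.DataFrame  # accession x environment effects


def gxe_anova(replicates: pd.DataFrame, trait: str) -> GxeAnovaResult:
    """Two-way mixed-model ANOVA of replicate trait values.

    Requires a balanced accession x environment design with >= 2 replicates
    per cell.  Following the random-genotype expected-mean-square
    convention, ENV and GEN are tested against the interaction mean square
    and the interaction against the residual.
    """
    df = replicates.dropna(subset=[trait])
    counts = df.groupby(["accession", "environment"], observed=True)[trait].count()
    accs = df["accession"].unique()
    envs = df["environment"].unique()
    if len(accs) < 2 or len(envs) != 2:
        raise ValueError("need >= 2 accessions and exactly 2 environments")
    if len(counts) != len(accs) * len(envs):
        raise ValueError("empty cells: the design must be complete")
    if counts.nunique() != 1 or counts.iloc[0] < 2:
        raise ValueError("design must be balanced with >= 2 replicates per cell")
    r = int(counts.iloc[0])
    a, e = len(accs), len(envs)

    y = df[trait].to_numpy(dtype=float)
    grand = y.mean()
    cell = df.groupby(["accession", "environment"], observed=True)[trait].mean().unstack()
    acc_mean = cell.mean(axis=1)
    env_mean = cell.mean(axis=0)
    ss_gen = e * r * float(((acc_mean - grand) ** 2).sum())
    ss_env = a * r * float(((env_mean - grand) ** 2).sum())
    inter = cell.sub(acc_mean, axis=0).sub(env_mean, axis=1) + grand
    ss_int = r * float((inter**2).to_numpy().sum())
    cell_of = df.set_index(["accession", "environment"]).index
    fitted = cell.stack().loc[cell_of].to_numpy()
    ss_err = float(((y - fitted) ** 2).sum())

    df_gen, df_env, df_int, df_err = a - 1, e - 1, (a - 1) * (e - 1), a * e * (r - 1)
    ms_gen, ms_env, ms_int, ms_err = (
        ss_gen / df_gen,
        ss_env / df_env,
        ss_int / df_int,
        ss_err / df_err,
    )
    f_gen = ms_gen / ms_int
    f_env = ms_env / ms_int
    f_int = ms_int / ms_err
    table = pd.DataFrame(
        {
            "ss": [ss_env, ss_gen, ss_int, ss_err],
            "df": [df_env, df_gen, df_int, df_err],
            "ms": [ms_env, ms_gen, ms_int, ms_err],
            "F": [f_env, f_gen, f_int, np.nan],
            "p": [
                stats.f.sf(f_env, df_env, df_int),
                stats.f.sf(f_gen, df_gen, df_int),
                stats.f.sf(f_int, df_int, df_err),
                np.nan,
            ],
        },
        index=["ENV", "GEN", "GENxENV", "ERROR"],
    )
    return GxeAnovaResult(anova=table, interaction_coefficients=inter)


@dataclass
class Heritability:
    h2: float
    var_genetic: float  # sigma_G^2 (within_env) or sigma_GxE^2 (plasticity)
    var_total: float
    components: dict[str, float]
    mode: str


def _oneway_reml(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """REML variance components (sigma_a2, sigma_e2) of y = mu + a_g + e.

    For balanced designs with an interior optimum the REML equations have
    the closed-form ANOVA (method-of-moments) solution, which is used
    directly; otherwise the restricted likelihood, expressed through the
    group means and the pooled within-group sum of squares, is maximised
    numerically.
    """
    y = np.asarray(y, dtype=float)
    codes, _ = pd.factorize(groups)
    g = codes.max() + 1
    if g < 2:
        raise ValueError("need at least two groups")
    ni = np.bincount(codes).astype(float)
    sums = np.bincount(codes, weights=y)
    ybar = sums / ni
    ss_w = float(np.sum((y - ybar[codes]) ** 2))
    N = float(len(y))

    if np.all(ni == ni[0]):
        rr = ni[0]
        mse = ss_w / (N - g) if N > g else 0.0
        msa = rr * float(np.sum((ybar - y.mean()) ** 2)) / (g - 1)
        sa2 = (msa - mse) / rr
        if sa2 >= 0:
            return float(sa2), float(mse)
        # boundary: sigma_a2 = 0, residual REML over all observations
        return 0.0, float(np.sum((y - y.mean()) ** 2) / (N - 1))

    def nll(theta: np.ndarray) -> float:
        sa2, se2 = np.exp(theta[0]) - 1e-12, np.exp(theta[1])
        v = sa2 + se2 / ni
        mu = np.sum(ybar / v) / np.sum(1.0 / v)
        return 0.5 * (
            (N - g) * np.log(se2)
            + ss_w / se2
            + float(np.sum(np.log(v)))
            + float(np.sum((ybar - mu) ** 2 / v))
            + np.log(float(np.sum(1.0 / v)))
        )

    mse = ss_w / max(N - g, 1.0)
    start = np.log([max(np.var(ybar, ddof=1), 1e-8), max(mse, 1e-8)])
    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 5000})
    sa2 = max(float(np.exp(res.x[0]) - 1e-12), 0.0)
    se2 = float(np.exp(res.x[1]))
    return sa2, se2


def heritability(
    replicates: pd.DataFrame, trait: str, mode: str = "within_env"
) -> Heritability:
    """Broad-sense heritability from REML variance components.

    ``within_env`` fits Phenotype = Accession(random) + Error on one
    environment's replicate data and returns H2 = sigma_G2 / sigma_P2.
    ``plasticity`` fits Accession + NitrogenLevel(fixed) +
    Accession-x-NitrogenLevel + Error on both environments and returns the
    interaction component's share of the phenotypic variance.  Negative
    component estimates are truncated at zero before forming the ratio.
    """
    df = replicates.dropna(subset=[trait])
    if df["accession"].nunique() < 2:
        raise ValueError("heritability undefined for a single accession")
    y = df[trait].to_numpy(dtype=float)

    if mode == "within_env":
        if df["environment"].nunique() != 1:
            raise ValueError("within_env mode needs data from a single environment")
        sa2, se2 = _oneway_reml(y, df["accession"].to_numpy())
        total = sa2 + se2
        h2 = sa2 / total if total > 0 else 0.0
        return Heritability(
            h2=float(np.clip(h2, 0.0, 1.0)),
            var_genetic=sa2,
            var_total=total,
            components={"accession": sa2, "residual": se2},
            mode=mode,
        )
    if mode != "plasticity":
        raise ValueError("mode must be 'within_env' or 'plasticity'")
    if df["environment"].nunique() != 2:
        raise ValueError("plasticity mode needs both environments")

    counts = df.groupby(["accession", "environment"], observed=True)[trait].count()
    a = df["accession"].nunique()
    balanced = (
        len(counts) == a * 2 and counts.nunique() == 1 and counts.iloc[0] >= 2
    )
    if balanced:
        r = int(counts.iloc[0])
        cell = df.groupby(["accession", "environment"], observed=True)[trait].mean().unstack()
        grand = y.mean()
        acc_mean = cell.mean(axis=1)
        env_mean = cell.mean(axis=0)
        ms_a = 2 * r * float(((acc_mean - grand) ** 2).sum()) / (a - 1)
        inter = cell.sub(acc_mean, axis=0).sub(env_mean, axis=1) + grand
        ms_axe = r * float((inter**2).to_numpy().sum()) / (a - 1)
        idx = df.set_index(["accession", "environment"]).index
        fitted = cell.stack().loc[idx].to_numpy()
        mse = float(((y - fitted) ** 2).sum()) / (a * 2 * (r - 1))
        s_axe = max((ms_axe - mse) / r, 0.0)
        s_a = max((ms_a - ms_axe) / (2 * r), 0.0)
        se2 = mse
    else:
        import statsmodels.formula.api as smf

        data = df[["accession", "environment", trait]].rename(columns={trait: "y"})
        md = smf.mixedlm(
            "y ~ C(environment)",
            data,
            groups="accession",
            re_formula="1",
            vc_formula={"axe": "0 + C(environment)"},
        )
        fit = md.fit(reml=True)
        s_a = max(float(fit.cov_re.iloc[0, 0]), 0.0)
        s_axe = max(float(fit.vcomp[0]), 0.0)
        se2 = float(fit.scale)
    total = s_a + s_axe + se2
    h2 = s_axe / total if total > 0 else 0.0
    return Heritability(
        h2=float(np.clip(h2, 0.0, 1.0)),
        var_genetic=s_axe,
        var_total=total,
        components={"accession": s_a, "interaction": s_axe, "residual": se2},
        mode=mode,
    )


def compare_mutant(mutant: np.ndarray, wild_type: np.ndarray) -> tuple[float, int]:
    """Pooled-variance two-tailed t-test of mutant versus wild-type values.

    Returns (p, direction) with direction the sign of mean(mutant) -
    mean(wild type).  Identical constant samples give p = 1.
    """
    a = np.asarray(mutant, dtype=float)
    b = np.asarray(wild_type, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    diff = a.mean() - b.mean()
    direction = int(np.sign(diff))
    res = stats.ttest_ind(a, b, equal_var=True)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0 if diff == 0 else 0.0
    return p, direction
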