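"""Probe-element outlier masking, robust summarisation and expression ANOVA.

Expression arrays designed against a reference genotype measure each gene
with a set of short probe elements; sequence variants in other accessions
can weaken the hybridisation of individual elements.  Because element
affinities are a fixed property of the probe set, the within-probe-set
rank order of element signals should be stable across arrays.  The outlier
procedure ranks elements within each probe set on each array, builds a
consensus ranking and an empirical null of rank deviations from the
reference accession's arrays, and flags (probe set, element, accession)
triples whose median rank drops significantly below the consensus in a
non-reference accession.  Masked probe sets are summarised with a one-step
Tukey biweight of the surviving log2 element signals and scaled per array
to a common trimmed mean.  Gene-level signals are then classified with a
two-factor ANOVA (accession x nitrogen treatment) followed by stepwise
model simplification under FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .traits import DendrogramPartition, cluster_rows

EFFECT_CLASSES = ("none", "AccessionOnly", "NOnly", "NAccession", "NxAccession")
DEFAULT_DETECTION_CUTOFF = 100.0


@dataclass
class SignalCube:
    """Positive probe-element signals for a full factorial array design.

    ``data`` is indexed by (probe_set, element) with a column MultiIndex
    (accession, treatment, replicate); ``reference_accession`` names the
    accession the array was designed against.
    """

    data: pd.DataFrame
    reference_accession: str

    def __post_init__(self) -> None:
        if (self.data.to_numpy() <= 0).any():
            raise ValueError("signals must be positive")
        self.data = self.data.sort_index(axis=0)
        if self.reference_accession not in self.accessions:
            raise ValueError("reference accession absent from cube")

    @property
    def accessions(self) -> list[str]:
        return list(self.data.columns.get_level_values("accession").unique())

    @property
    def probe_sets(self) -> list[str]:
        return list(self.data.index.get_level_values("probe_set").unique())

    def grouped_by_element_count(self):
        """Yield (k, probe ids, values (n_ps, k, n_arrays)) per element count."""
        counts = self.data.groupby(level="probe_set", sort=False).size()
        for k in sorted(counts.unique()):
            ids = list(counts.index[counts == k])
            arr = self.data.loc[ids].to_numpy().reshape(len(ids), int(k), -1)
            yield int(k), ids, arr


@dataclass
class RankNull:
    """Reference-accession consensus rankings plus an empirical null.

    The detection statistic for a (probe set, element, accession) triple is
    the mean, over the accession's arrays, of (consensus rank - observed
    rank) — positive when the element's hybridisation rank has dropped.
    Its null distribution is built by permutation: under no sequence
    divergence the reference and tested arrays are exchangeable with
    respect to the fixed element-affinity geometry, so reference and
    tested arrays are pooled, randomly reassigned, the consensus recomputed
    from the reassigned "reference" half and the statistic from the other
    half, with draws pooled across probe sets (stratified by element
    count).  This keeps each element's tie geometry — the dominant source
    of rank jitter — inside the null.
    """

    consensus: dict[str, np.ndarray]
    pooled_deviations: dict[int, np.ndarray]  # per-array deviations (diagnostics)
    null_stats: dict[int, np.ndarray]  # permutation draws of the statistic
    n_arrays_per_accession: int

    def threshold(self, n_elements: int, alpha: float) -> float:
        draws = self.null_stats[n_elements]
        return float(np.quantile(draws, 1.0 - alpha))


def build_rank_null(
    cube: SignalCube, n_permutations: int = 4, seed: int = 0
) -> RankNull:
    """Build consensus element rankings and the rank-deviation null.

    The consensus uses only the reference accession's arrays; the
    permutation null pools the reference arrays with each non-reference
    accession's arrays in turn and reassigns them ``n_permutations`` times.
    Probe sets with a single element carry no ranking information and are
    excluded.
    """
    acc_of_col = cube.data.columns.get_level_values("accession").to_numpy()
    ref_cols = acc_of_col == cube.reference_accession
    n_ref = int(ref_cols.sum())
    if n_ref < 2:
        raise ValueError("reference accession needs at least two arrays")
    others = [a for a in cube.accessions if a != cube.reference_accession]
    rng = np.random.default_rng(seed)
    consensus: dict[str, np.ndarray] = {}
    pooled: dict[int, list[np.ndarray]] = {}
    null: dict[int, list[np.ndarray]] = {}
    for k, ids, arr in cube.grouped_by_element_count():
        if k < 2:
            continue
        rranks = stats.rankdata(arr[:, :, ref_cols], axis=1)
        cons = np.median(rranks, axis=2)  # (n_ps, k)
        for i, ps in enumerate(ids):
            consensus[str(ps)] = cons[i]
        pooled.setdefault(k, []).append((cons[:, :, None] - rranks).ravel())
        for acc in others:
            both = np.concatenate(
                [arr[:, :, ref_cols], arr[:, :, acc_of_col == acc]], axis=2
            )
            n_tot = both.shape[2]
            for _ in range(n_permutations):
                idx = rng.permutation(n_tot)
                pr = stats.rankdata(both[:, :, idx[:n_ref]], axis=1)
                pc = np.median(pr, axis=2)
                tr = stats.rankdata(both[:, :, idx[n_ref:]], axis=1)
                null.setdefault(k, []).append(
                    (pc[:, :, None] - tr).mean(axis=2).ravel()
                )
    if not consensus:
        raise ValueError("no multi-element probe sets in the cube")
    return RankNull(
        consensus=consensus,
        pooled_deviations={k: np.concatenate(v) for k, v in pooled.items()},
        null_stats={k: np.concatenate(v) for k, v in null.items()},
        n_arrays_per_accession=cube.data.shape[1] // len(cube.accessions),
    )


@dataclass
class OutlierMask:
    """Flagged (probe set, element, accession) triples."""

    flagged: set[tuple[str, int, str]]
    table: pd.DataFrame  # probe_set, element, accession, statistic, threshold

    def __contains__(self, triple: tuple[str, int, str]) -> bool:
        return triple in self.flagged


def detect_outlier_elements(
    cube: SignalCube, null: RankNull, alpha: float = 0.01
) -> OutlierMask:
    """Flag probe elements whose rank drops in a non-reference accession.

    For every non-reference accession, the statistic per element is the
    mean over that accession's arrays of (consensus rank - observed rank);
    the element is flagged when the statistic exceeds the (1 - alpha)
    quantile of the permutation null for its probe set's element count.
    The test is one-sided toward rank decrease, since sequence mismatches
    weaken hybridisation.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    flagged: set[tuple[str, int, str]] = set()
    rows = []
    others = [a for a in cube.accessions if a != cube.reference_accession]
    acc_of_col = cube.data.columns.get_level_values("accession").to_numpy()
    for k, ids, arr in cube.grouped_by_element_count():
        if k < 2 or k not in null.null_stats:
            continue
        cons = np.stack([null.consensus[str(ps)] for ps in ids])
        thr = null.threshold(k, alpha)
        for acc in others:
            ranks = stats.rankdata(arr[:, :, acc_of_col == acc], axis=1)
            stat = (cons[:, :, None] - ranks).mean(axis=2)
            for i, e in zip(*np.nonzero(stat > thr)):
                flagged.add((str(ids[i]), int(e), acc))
                rows.append(
                    {
                        "probe_set": str(ids[i]),
                        "element": int(e),
                        "accession": acc,
                        "statistic": float(stat[i, e]),
                        "threshold": thr,
                    }
                )
    table = pd.DataFrame(rows, columns=["probe_set", "element", "accession",
                                        "statistic", "threshold"])
    return OutlierMask(flagged=flagged, table=table)


def _tukey_biweight(x: np.ndarray, c: float = 5.0, eps: float = 1e-4) -> np.ndarray:
    """One-step Tukey biweight location along axis 1, ignoring NaN."""
    med = np.nanmedian(x, axis=1, keepdims=True)
    mad = np.nanmedian(np.abs(x - med), axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        u = (x - med) / (c * mad + eps)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    w = np.where(np.isnan(x), 0.0, w)
    xz = np.where(np.isnan(x), 0.0, x)
    with np.errstate(invalid="ignore"):
        return np.sum(w * xz, axis=1) / np.sum(w, axis=1)


@dataclass
class ExpressionMatrix:
    """Summarised probe-set signals per array, after masking and scaling."""

    values: pd.DataFrame  # probe_set x (accession, treatment, replicate)
    elements_used: pd.DataFrame  # probe_set x accession element counts
    scale_factors: pd.Series


def summarize_probesets(
    cube: SignalCube,
    mask: OutlierMask | None = None,
    min_elements: int = 3,
    scale: bool = True,
    scale_target: float = 500.0,
) -> ExpressionMatrix:
    """Summarise each probe set per array, excluding masked elements.

    Per (probe set, array) the summary is a one-step Tukey biweight of the
    log2 element signals surviving the mask for that array's accession,
    exponentiated back to the signal scale.  Probe sets left with fewer
    than ``min_elements`` elements for an accession are set missing for all
    of that accession's arrays.  With ``scale`` True, arrays are rescaled
    so every array's median summary equals the fixed ``scale_target`` — a
    robust scale normalisation that removes per-array brightness
    differences exactly and, unlike a trimmed mean on the natural scale,
    is insensitive to the minority of genes with real treatment or
    accession effects.  Rescaling all of one array's elements by a common
    factor therefore leaves its normalised output unchanged.
    """
    flagged = mask.flagged if mask is not None else set()
    accs = cube.accessions
    cols = cube.data.columns
    acc_of_col = cols.get_level_values("accession").to_numpy()
    acc_col_idx = {acc: np.flatnonzero(acc_of_col == acc) for acc in accs}
    frames = []
    used_rows = {}
    for k, ids, arr in cube.grouped_by_element_count():
        logv = np.log2(arr)  # (n_ps, k, n_arrays)
        keep = np.ones((len(ids), k, len(accs)), dtype=bool)
        if flagged:
            id_pos = {ps: i for i, ps in enumerate(ids)}
            for a_i, acc in enumerate(accs):
                for ps, e, facc in flagged:
                    if facc == acc and ps in id_pos:
                        keep[id_pos[ps], e, a_i] = False
        x = np.full_like(logv, np.nan)
        for a_i, acc in enumerate(accs):
            jj = acc_col_idx[acc]
            x[:, :, jj] = np.where(keep[:, :, a_i][:, :, None], logv[:, :, jj], np.nan)
        n_keep = keep.sum(axis=1)  # (n_ps, n_accs)
        summary = np.empty((len(ids), len(cols)))
        for j in range(len(cols)):
            summary[:, j] = _tukey_biweight(x[:, :, j])
        for a_i, acc in enumerate(accs):
            bad = n_keep[:, a_i] < min_elements
            summary[np.ix_(bad, acc_col_idx[acc])] = np.nan
        frames.append(pd.DataFrame(2.0**summary, index=pd.Index(ids, name="probe_set"),
                                   columns=cols))
        for i, ps in enumerate(ids):
            used_rows[ps] = dict(zip(accs, n_keep[i].tolist()))
    values = pd.concat(frames).reindex(cube.probe_sets)
    dropped = values.isna().all(axis=1)
    if dropped.any():
        warnings.warn(f"{int(dropped.sum())} probe sets fully masked")
    if scale:
        med = np.log2(values).median(axis=0, skipna=True)
        shift = np.log2(scale_target) - med
        factors = 2.0**shift
        values = values.mul(factors, axis=1)
    else:
        factors = pd.Series(1.0, index=cols)
    elements_used = pd.DataFrame.from_dict(used_rows, orient="index")
    elements_used.index.name = "probe_set"
    return ExpressionMatrix(values=values, elements_used=elements_used,
                            scale_factors=factors)


def flag_probes(
    annotation: pd.DataFrame,
    expr: ExpressionMatrix,
    detection_cutoff: float = DEFAULT_DETECTION_CUTOFF,
) -> pd.DataFrame:
    """Assign quality flags 1-4 to probe sets.

    ``annotation`` is indexed by probe set with columns ``gene_id`` (comma
    separated for multi-gene matches, empty/NaN for no match) and an
    optional boolean ``nuclear``.  Flags: 1 = non-nuclear or no gene match
    (also applied to probes absent from the annotation), 2 = matches more
    than one gene, 3 = gene targeted by several probe sets, 4 = mean
    summarised signal across all arrays below the detection cutoff.  The
    returned frame carries one boolean column per flag plus ``analysis_set``
    (True iff none of flags 1, 2, 4 apply).
    """
    probes = expr.values.index
    ann = annotation.reindex(probes)
    gene_str = ann["gene_id"].fillna("")
    nuclear = ann["nuclear"].fillna(True) if "nuclear" in ann else pd.Series(True, index=probes)
    genes_per_probe = gene_str.map(lambda s: [g for g in str(s).split(",") if g])
    flag1 = (genes_per_probe.map(len) == 0) | (~nuclear.astype(bool))
    flag2 = genes_per_probe.map(len) > 1
    single = genes_per_probe[genes_per_probe.map(len) == 1].map(lambda g: g[0])
    dup_genes = single[single.duplicated(keep=False)]
    flag3 = pd.Series(False, index=probes)
    flag3.loc[dup_genes.index] = True
    mean_sig = expr.values.mean(axis=1, skipna=True)
    flag4 = mean_sig < detection_cutoff
    out = pd.DataFrame(
        {"flag1": flag1, "flag2": flag2, "flag3": flag3, "flag4": flag4.fillna(True)}
    )
    out["analysis_set"] = ~(out["flag1"] | out["flag2"] | out["flag4"])
    out["gene_id"] = gene_str
    return out


def _bh_reject(p: np.ndarray, fdr: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p)
    thresh = fdr * np.arange(1, m + 1) / m
    passing = p[order] <= thresh
    k = np.max(np.flatnonzero(passing)) + 1 if passing.any() else 0
    out = np.zeros(m, dtype=bool)
    out[order[:k]] = True
    return out


@dataclass
class GeneEffectTable:
    """Per-gene effect classification from ANOVA model simplification."""

    classes: pd.DataFrame  # class, p_model, p_interaction, p_treatment, p_accession
    responses: pd.DataFrame  # gene x accession mean log2 response (control - treated)


def anova_classify(
    expr: ExpressionMatrix | pd.DataFrame,
    fdr: float = 0.1,
    gene_map: pd.Series | None = None,
) -> GeneEffectTable:
    """Classify genes by two-factor ANOVA with model simplification.

    Signals are analysed on the log2 scale.  Stage 1 fits the full
    accession x treatment model with interaction per gene and keeps genes
    whose overall model F-test passes Benjamini-Hochberg at ``fdr``.
    Stage 2 runs nested F comparisons dropping one term at a time
    (interaction first, then treatment, then accession), each family
    BH-corrected at the same level, and assigns: interaction retained ->
    NxAccession; else treatment and accession -> NAccession; treatment
    only -> NOnly; accession only -> AccessionOnly; none -> none.
    Genes with missing cells are skipped with a warning.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    cols = values.columns
    accs = cols.get_level_values("accession").unique()
    trts = cols.get_level_values("treatment").unique()
    reps = cols.get_level_values("replicate").unique()
    A, T, R = len(accs), len(trts), len(reps)
    if A < 2 or T != 2 or R < 2:
        raise ValueError("need >= 2 accessions, 2 treatments and >= 2 replicates")
    ordered = values.reindex(
        columns=pd.MultiIndex.from_product([accs, trts, reps], names=cols.names)
    )
    complete = ordered.notna().all(axis=1)
    if (~complete).any():
        warnings.warn(f"{int((~complete).sum())} genes with missing cells skipped")
    Y = np.log2(ordered.loc[complete].to_numpy()).reshape(-1, A, T, R)
    G = Y.shape[0]

    cell = Y.mean(axis=3)
    grand = cell.mean(axis=(1, 2))
    am = cell.mean(axis=2)
    tm = cell.mean(axis=1)
    ss_acc = T * R * ((am - grand[:, None]) ** 2).sum(axis=1)
    ss_trt = A * R * ((tm - grand[:, None]) ** 2).sum(axis=1)
    inter = cell - am[:, :, None] - tm[:, None, :] + grand[:, None, None]
    ss_int = R * (inter**2).sum(axis=(1, 2))
    ss_err = ((Y - cell[:, :, :, None]) ** 2).sum(axis=(1, 2, 3))
    df_model, df_err = A * T - 1, A * T * (R - 1)
    df_acc, df_trt, df_int = A - 1, T - 1, (A - 1) * (T - 1)
    ms_err = ss_err / df_err

    with np.errstate(divide="ignore", invalid="ignore"):
        f_model = (ss_acc + ss_trt + ss_int) / df_model / ms_err
    p_model = np.where(np.isfinite(f_model), stats.f.sf(f_model, df_model, df_err), 1.0)
    p_model = np.where((ss_acc + ss_trt + ss_int + ss_err) == 0, 1.0, p_model)

    stage1 = _bh_reject(p_model, fdr)
    cls = np.zeros(G, dtype=int)  # index into EFFECT_CLASSES
    p_int = np.full(G, np.nan)
    p_trt = np.full(G, np.nan)
    p_acc = np.full(G, np.nan)

    sel = np.flatnonzero(stage1)
    if len(sel):
        with np.errstate(divide="ignore", invalid="ignore"):
            f_int = (ss_int[sel] / df_int) / ms_err[sel]
        pi = np.where(np.isfinite(f_int), stats.f.sf(f_int, df_int, df_err), 1.0)
        p_int[sel] = pi
        int_sig = _bh_reject(pi, fdr)
        cls[sel[int_sig]] = 4  # NxAccession

        add = sel[~int_sig]
        if len(add):
            ss_res_add = ss_err[add] + ss_int[add]
            df_res_add = df_err + df_int
            ms_res_add = ss_res_add / df_res_add
            with np.errstate(divide="ignore", invalid="ignore"):
                ft = (ss_trt[add] / df_trt) / ms_res_add
                fa = (ss_acc[add] / df_acc) / ms_res_add
            pt = np.where(np.isfinite(ft), stats.f.sf(ft, df_trt, df_res_add), 1.0)
            pa = np.where(np.isfinite(fa), stats.f.sf(fa, df_acc, df_res_add), 1.0)
            p_trt[add] = pt
            p_acc[add] = pa
            trt_sig = _bh_reject(pt, fdr)
            acc_sig = _bh_reject(pa, fdr)
            cls[add[trt_sig & acc_sig]] = 3  # NAccession
            cls[add[trt_sig & ~acc_sig]] = 2  # NOnly
            cls[add[~trt_sig & acc_sig]] = 1  # AccessionOnly

    idx = values.index[complete]
    responses = pd.DataFrame(
        Y.mean(axis=3)[:, :, 0] - Y.mean(axis=3)[:, :, 1], index=idx, columns=accs
    )
    table = pd.DataFrame(
        {
            "class": [EFFECT_CLASSES[c] for c in cls],
            "p_model": p_model,
            "p_interaction": p_int,
            "p_treatment": p_trt,
            "p_accession": p_acc,
        },
        index=idx,
    )
    if gene_map is not None:
        table.insert(0, "gene_id", gene_map.reindex(idx))
    return GeneEffectTable(classes=table, responses=responses)


def response_profiles(
    expr: ExpressionMatrix | pd.DataFrame,
    control: str = "control",
    treated: str = "treated",
) -> pd.DataFrame:
    """Per-gene mean log2 response (control minus treated) per accession."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    logv = np.log2(values)
    ctrl = logv.xs(control, axis=1, level="treatment").T.groupby(level="accession").mean().T
    trt = logv.xs(treated, axis=1, level="treatment").T.groupby(level="accession").mean().T
    return ctrl - trt


def cluster_effect_genes(
    expr: ExpressionMatrix | pd.DataFrame,
    classes: pd.Series,
) -> dict[str, tuple[pd.DataFrame, DendrogramPartition | None]]:
    """Cluster per-class genes on normalised per-treatment expression shapes.

    Per class (excluding "none"): expression is averaged per (accession,
    treatment), log2 converted and row mean-centred, then clustered with
    average linkage on 1 - Pearson with a silhouette-selected cut.
    Classes with fewer than 3 genes form a single cluster.  Returns, per
    class, the normalised matrix and the partition (None when trivial).
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    logv = np.log2(values)
    per_cell = logv.T.groupby(level=["accession", "treatment"], sort=False).mean().T
    out: dict[str, tuple[pd.DataFrame, DendrogramPartition | None]] = {}
    for cls in classes.unique():
        if cls == "none":
            continue
        genes = classes.index[classes == cls]
        mat = per_cell.loc[per_cell.index.intersection(genes)]
        mat = mat.sub(mat.mean(axis=1), axis=0)
        if len(mat) < 3:
            out[cls] = (mat, None)
            continue
        out[cls] = (mat, cluster_rows(mat))
    return out
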