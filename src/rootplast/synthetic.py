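"""Synthetic study generators with ground-truth records.

Three generators emulate the statistical structure of the study design:

* inbred genotype panels with subpopulation structure (Balding-Nichols
  style allele-frequency divergence around a shared ancestral frequency);
* replicate-level root measurements whose primary-root trait follows an
  additive accession + environment + interaction + residual decomposition
  with optional planted causal SNPs, and whose lateral-root system is
  drawn from Poisson counts and gamma lengths coupled to the same latent
  growth factor;
* probe-element expression cubes (accessions x treatments x replicates)
  with fixed per-element affinities, planted per-class gene effects on the
  log2 scale, and planted SNP-attenuated elements in non-reference
  accessions.

Each generator is a pure function of its arguments plus an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import SignalCube
from .gwas import GenotypeMatrix
from .traits import RootMeasurement, TraitTable, derive_traits

GENE_CLASSES = ("none", "AccessionOnly", "NOnly", "NAccession", "NxAccession")

DEFAULT_REFERENCE_ACCESSION = "acc001"


@dataclass
class CausalSnp:
    snp_id: str
    effect_sd: float  # additive effect in within-environment trait-SD units
    env_specific: bool = False  # if True, acts in highN only


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside each synthetic dataset."""

    seed: int
    causal_snps: list[CausalSnp] = field(default_factory=list)
    variance_components: dict[str, float] = field(default_factory=dict)
    gene_classes: dict[str, str] = field(default_factory=dict)
    attenuated_elements: set[tuple[str, int, str, float]] = field(default_factory=set)
    subpop_labels: dict[str, int] = field(default_factory=dict)
    noise_free_log2: "pd.DataFrame | None" = None  # expression cube sans noise


def simulate_genotypes(
    n_accessions: int,
    n_snps: int,
    n_subpops: int = 1,
    divergence: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    n_chromosomes: int = 5,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Simulate an inbred biallelic SNP panel with population structure.

    Ancestral allele frequencies are uniform on [0.1, 0.9]; each
    subpopulation's frequency is beta-distributed around the ancestral one
    with divergence parameter F (variance F * p * (1 - p)), and inbred
    accessions carry a single Bernoulli draw per SNP.  Positions are
    strictly increasing within chromosomes.
    """
    if n_accessions < 2 or n_snps < 1:
        raise ValueError("need n_accessions >= 2 and n_snps >= 1")
    if not 0 <= divergence < 1:
        raise ValueError("divergence must lie in [0, 1)")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    if n_subpops < 1:
        raise ValueError("n_subpops must be >= 1")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.1, 0.9, size=n_snps)
    if n_subpops > 1 and divergence > 0:
        c = (1.0 - divergence) / divergence
        pf = rng.beta(
            anc[None, :] * c, (1.0 - anc)[None, :] * c, size=(n_subpops, n_snps)
        )
    else:
        pf = np.tile(anc, (n_subpops, 1))
    subpop = np.arange(n_accessions) % n_subpops
    calls = (rng.random((n_accessions, n_snps)) < pf[subpop]).astype(float)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = np.nan

    chroms = 1 + (np.arange(n_snps) * n_chromosomes) // n_snps
    pos = np.empty(n_snps, dtype=int)
    for c in range(1, n_chromosomes + 1):
        idx = np.flatnonzero(chroms == c)
        steps = rng.integers(100, 5000, size=len(idx))
        pos[idx] = np.cumsum(steps)
    snp_ids = [f"chr{c}_{p}" for c, p in zip(chroms, pos)]
    accs = [f"acc{i + 1:03d}" for i in range(n_accessions)]
    snps = pd.DataFrame(
        {"chrom": [f"chr{c}" for c in chroms], "pos": pos}, index=pd.Index(snp_ids, name="snp")
    )
    gm = GenotypeMatrix(
        snps=snps, calls=pd.DataFrame(calls.T, index=snps.index, columns=accs)
    )
    truth = SyntheticTruth(seed=seed, subpop_labels=dict(zip(accs, subpop.tolist())))
    return gm, truth


def simulate_root_traits(
    genotypes: GenotypeMatrix,
    variance_components: dict[str, float] | None = None,
    causal_snps: list[CausalSnp] | None = None,
    n_replicates: int = 10,
    seed: int = 0,
    pr_base: float = 5.0,
) -> tuple[list[RootMeasurement], TraitTable, SyntheticTruth]:
    """Simulate replicate root measurements for a genotyped panel.

    ``variance_components`` gives the accession, environment, interaction
    and residual variances of the latent growth factor in cm^2 (defaults
    0.5 / 0.5 / 0.2 / 0.5).  The primary-root length carries the latent
    factor additively, so its variance decomposition equals the
    specification exactly; lateral-root counts (Poisson, environment-
    dependent mean) and lengths (gamma) are coupled to the same factor so
    derived traits covary realistically.  Causal SNP effects are expressed
    in units of the within-environment phenotypic standard deviation and
    added to the latent factor of carrier accessions.  With zero residual
    variance all replicate-level draws collapse to their means.
    """
    vc = {"accession": 0.5, "environment": 0.5, "interaction": 0.2, "residual": 0.5}
    if variance_components:
        vc.update(variance_components)
    if any(v < 0 for v in vc.values()):
        raise ValueError("variance components must be >= 0")
    causal_snps = list(causal_snps or [])
    for cs in causal_snps:
        if cs.snp_id not in genotypes.snps.index:
            raise ValueError(f"causal SNP {cs.snp_id} absent from genotypes")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    accs = genotypes.accessions
    n = len(accs)
    sd_within = float(np.sqrt(vc["accession"] + vc["interaction"] + vc["residual"]))
    if sd_within == 0:
        sd_within = 1.0

    a = rng.normal(0.0, np.sqrt(vc["accession"]), size=n)
    ae = rng.normal(0.0, np.sqrt(vc["interaction"]), size=(n, 2))
    env_off = {"lowN": -np.sqrt(vc["environment"]), "highN": np.sqrt(vc["environment"])}
    snp_shift = np.zeros((n, 2))
    for cs in causal_snps:
        g = genotypes.calls.loc[cs.snp_id].reindex(accs).fillna(0.0).to_numpy()
        shift = cs.effect_sd * sd_within * g
        snp_shift[:, 1] += shift
        if not cs.env_specific:
            snp_shift[:, 0] += shift

    deterministic = vc["residual"] == 0
    lr_count_base = {"lowN": 4.0, "highN": 8.0}
    lr_len_base = {"lowN": 0.6, "highN": 1.0}
    lb_frac_mean = 5.0 / 7.0

    measurements: list[RootMeasurement] = []
    for i, acc in enumerate(accs):
        for j, env in enumerate(("lowN", "highN")):
            u = a[i] + env_off[env] + ae[i, j] + snp_shift[i, j]
            lam = max(lr_count_base[env] * (1.0 + 0.10 * u), 0.0)
            mean_len = max(lr_len_base[env] * (1.0 + 0.10 * u), 0.01)
            for r in range(n_replicates):
                eps = 0.0 if deterministic else rng.normal(0.0, np.sqrt(vc["residual"]))
                pr = max(pr_base + u + eps, 0.05)
                if deterministic:
                    count = int(round(lam))
                    lengths = [mean_len] * count
                else:
                    count = int(rng.poisson(lam))
                    lengths = (
                        rng.gamma(4.0, mean_len / 4.0, size=count).tolist() if count else []
                    )
                if count > 0:
                    frac = lb_frac_mean if deterministic else float(rng.beta(5.0, 2.0))
                    lb = min(frac * pr, pr)
                else:
                    lb = 0.0
                measurements.append(
                    RootMeasurement(
                        accession=acc,
                        environment=env,
                        replicate=r + 1,
                        pr=pr,
                        lr_lengths=[float(x) for x in lengths],
                        branching_zone=lb,
                    )
                )
    table = derive_traits(measurements)
    truth = SyntheticTruth(
        seed=seed, causal_snps=causal_snps, variance_components=dict(vc)
    )
    return measurements, table, truth


def simulate_expression_study(
    n_genes: int,
    class_proportions: tuple[float, float, float, float, float] = (0.6, 0.2, 0.05, 0.05, 0.1),
    effect_size: float = 2.0,
    n_accessions: int = 7,
    n_elements: int = 11,
    n_replicates: int = 3,
    attenuation_spec: dict | list | None = None,
    noise_sd: float = 0.25,
    affinity_sd: float = 1.0,
    seed: int = 0,
) -> tuple[SignalCube, pd.DataFrame, SyntheticTruth]:
    """Simulate a probe-element expression study with planted structure.

    ``class_proportions`` orders the five effect classes (none,
    AccessionOnly, NOnly, NAccession, NxAccession) and must sum to 1.
    Gene-level log2 means follow the assigned class with characteristic
    magnitude ``effect_size`` (log2 units); element signals multiply the
    gene signal by a fixed log-normal per-(probe set, element) affinity
    (log2 SD ``affinity_sd``), any planted attenuation fraction, and
    multiplicative log-normal noise of log2 SD ``noise_sd``.

    ``attenuation_spec`` plants outlier elements, either as an explicit
    list of (probe_set, element, accession, fraction) tuples or as a dict
    {"n_outliers": int, "fraction": float, "min_affinity_rank": int}.  In
    dict form the affected (probe set, element, non-reference accession)
    triples are sampled uniformly among elements whose within-probe-set
    affinity rank (ascending; 1 = weakest) is at least ``min_affinity_rank``
    (default 4): an element already at the bottom of the ranking has no
    rank headroom and a rank-decrease statistic cannot register it.

    The first accession is the reference (no attenuation is planted on it).
    Returns the signal cube, a probe -> gene map and the truth record.
    """
    props = np.asarray(class_proportions, dtype=float)
    if props.shape != (5,) or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
        raise ValueError("class_proportions must be 5 non-negative fractions summing to 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if n_genes < 1 or n_accessions < 2 or n_elements < 1 or n_replicates < 1:
        raise ValueError("counts must be positive (>= 2 accessions)")
    rng = np.random.default_rng(seed)
    accs = [f"acc{i + 1:03d}" for i in range(n_accessions)]
    treatments = ("control", "treated")

    counts = np.floor(props * n_genes).astype(int)
    while counts.sum() < n_genes:
        counts[int(np.argmax(props * n_genes - counts))] += 1
    classes = np.repeat(np.arange(5), counts)
    rng.shuffle(classes)

    base = rng.normal(9.0, 1.0, size=n_genes)
    # cell log2 means per gene: (gene, accession, treatment)
    mu = np.tile(base[:, None, None], (1, n_accessions, 2))
    for g in range(n_genes):
        cls = GENE_CLASSES[classes[g]]
        if cls in ("AccessionOnly", "NAccession", "NxAccession"):
            mu[g] += rng.normal(0.0, effect_size, size=n_accessions)[:, None]
        if cls == "NOnly" or cls == "NAccession":
            resp = effect_size * rng.choice([-1.0, 1.0])
            mu[g, :, 1] += resp
        elif cls == "NxAccession":
            mu[g, :, 1] += rng.normal(0.0, effect_size, size=n_accessions)

    affinity = rng.normal(0.0, affinity_sd, size=(n_genes, n_elements))

    atten = np.zeros((n_genes, n_elements, n_accessions))
    truth_atten: set[tuple[str, int, str, float]] = set()
    probes = [f"PS{g + 1:05d}_at" for g in range(n_genes)]
    genes = [f"GENE{g + 1:05d}" for g in range(n_genes)]
    planted: list[tuple[int, int, int, float]] = []
    if isinstance(attenuation_spec, dict):
        n_out = int(attenuation_spec.get("n_outliers", 0))
        frac = float(attenuation_spec.get("fraction", 0.4))
        min_rank = int(attenuation_spec.get("min_affinity_rank", 4))
        if not 0 < frac <= 1:
            raise ValueError("attenuation fraction must lie in (0, 1]")
        ranks = affinity.argsort(axis=1).argsort(axis=1) + 1  # 1 = weakest
        eligible = [
            (g, e)
            for g in range(n_genes)
            for e in range(n_elements)
            if ranks[g, e] >= min_rank
        ]
        pick_ge = rng.choice(len(eligible), size=min(n_out, len(eligible)), replace=False)
        for k in np.atleast_1d(pick_ge):
            g, e = eligible[int(k)]
            acc_i = int(rng.integers(1, n_accessions))  # never the reference
            planted.append((g, e, acc_i, frac))
    elif attenuation_spec:
        probe_index = {p: i for i, p in enumerate(probes)}
        acc_index = {a: i for i, a in enumerate(accs)}
        for probe, elem, acc, frac in attenuation_spec:
            if not 0 < frac <= 1:
                raise ValueError("attenuation fraction must lie in (0, 1]")
            planted.append((probe_index[probe], int(elem), acc_index[acc], float(frac)))
    for g, e, acc_i, frac in planted:
        if acc_i == 0:
            raise ValueError("cannot plant attenuation on the reference accession")
        atten[g, e, acc_i] = np.log2(frac)
        truth_atten.add((probes[g], e, accs[acc_i], frac))

    arrays = [(ai, ti, ri) for ai in range(n_accessions) for ti in range(2)
              for ri in range(n_replicates)]
    brightness = rng.normal(0.0, 0.1, size=len(arrays))  # per-array technical scale
    noise = rng.normal(0.0, noise_sd, size=(n_genes, n_elements, len(arrays)))
    log2sig = np.empty_like(noise)
    for k, (ai, ti, _) in enumerate(arrays):
        log2sig[:, :, k] = (
            mu[:, ai, ti][:, None] + affinity + atten[:, :, ai]
            + brightness[k] + noise[:, :, k]
        )
    signal = 2.0**log2sig

    cols = pd.MultiIndex.from_tuples(
        [(accs[ai], treatments[ti], ri + 1) for ai, ti, ri in arrays],
        names=["accession", "treatment", "replicate"],
    )
    idx = pd.MultiIndex.from_product(
        [probes, range(n_elements)], names=["probe_set", "element"]
    )
    data = pd.DataFrame(
        signal.reshape(n_genes * n_elements, len(arrays)), index=idx, columns=cols
    )
    cube = SignalCube(data=data, reference_accession=accs[0])
    probe_map = pd.DataFrame({"probe_set": probes, "gene_id": genes}).set_index("probe_set")
    truth = SyntheticTruth(
        seed=seed,
        gene_classes={genes[g]: GENE_CLASSES[classes[g]] for g in range(n_genes)},
        attenuated_elements=truth_atten,
        noise_free_log2=pd.DataFrame(
            (log2sig - noise).reshape(n_genes * n_elements, len(arrays)),
            index=idx, columns=cols,
        ),
    )
    return cube, probe_map, truth
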