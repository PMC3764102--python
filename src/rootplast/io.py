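"""Readers/writers for the pipeline's interchange formats, plus the runner.

All tables travel as TSV with header rows.  Internal coordinates are
1-based inclusive everywhere; BED input (0-based half-open) is converted at
the boundary.  Every writer/reader pair round-trips values exactly.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gwas, network, synthetic, traits
from . import expression as expr_mod
from .expression import ExpressionMatrix, SignalCube
from .gwas import GeneModel, GenotypeMatrix
from .traits import ScaledTraitMatrix, TraitTable

logger = logging.getLogger("rootplast")

DEFAULT_CONFIG = {
    "seed": 0,
    "maf_threshold": 0.1,
    "q_threshold": 0.05,
    "expression_fdr": 0.1,
    "detection_cutoff": 100.0,
    "window_half_width": 10_000,
    "edge_r": 0.7,
    "cluster_null_percentile": 0.10,
    "outlier_alpha": 0.01,
    "n_accessions": 48,
    "n_snps": 2000,
    "n_subpops": 3,
    "divergence": 0.15,
    "n_replicates": 10,
    "n_genes": 400,
    "scan_traits": ["LRlengthave", "PR"],
    "power_reps": 100,
    "power_mafs": [0.1, 0.3, 0.5],
    "accession_subset": None,
}


# ---------------------------------------------------------------- trait tables

def write_trait_table(table: TraitTable, path: str | Path) -> None:
    table.replicates.to_csv(path, sep="\t", index=False)


def read_trait_table(path: str | Path) -> TraitTable:
    reps = pd.read_csv(path, sep="\t")
    required = {"accession", "environment", "replicate"}
    if not required <= set(reps.columns):
        raise ValueError(f"{path}: missing columns {required - set(reps.columns)}")
    dup = reps.duplicated(subset=["accession", "environment", "replicate"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (accession, environment, replicate) keys "
                         f"at rows {list(reps.index[dup] + 2)}")
    bad = ~reps["environment"].isin(traits.ENVIRONMENTS)
    if bad.any():
        raise ValueError(f"{path}: unknown environment labels at rows "
                         f"{list(reps.index[bad] + 2)}")
    grouped = reps.groupby(["accession", "environment"])[traits.TRAIT_NAMES]
    means = grouped.mean()
    n = grouped.size().rename("n")
    se = grouped.std(ddof=1).div(np.sqrt(n), axis=0)
    se[n < 2] = np.nan
    return TraitTable(replicates=reps, means=means, se=se, n=n)


def write_scaled_matrix(sm: ScaledTraitMatrix, path: str | Path) -> None:
    """Matrix as TSV plus anchors in a sidecar JSON for lossless round-trip."""
    path = Path(path)
    sm.values.to_csv(path, sep="\t", index_label="row")
    sidecar = {
        "missing_policy": sm.missing_policy,
        "index_name": sm.values.index.name,
        "anchors": {c: [sm.anchors.loc[c, "low"], sm.anchors.loc[c, "high"]]
                    for c in sm.anchors.index},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_scaled_matrix(path: str | Path) -> ScaledTraitMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="row")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    values.index.name = meta.get("index_name")
    anchors = pd.DataFrame(meta["anchors"], index=["low", "high"]).T
    return ScaledTraitMatrix(values=values, anchors=anchors,
                             missing_policy=meta["missing_policy"])


# ------------------------------------------------------------------ genotypes

def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    out = pd.concat([gm.snps, gm.calls], axis=1)
    out.to_csv(path, sep="\t", index_label="snp", na_rep="NA")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="snp", na_values=["NA"])
    if "chrom" not in df or "pos" not in df:
        raise ValueError(f"{path}: genotype TSV needs chrom and pos columns")
    snps = df[["chrom", "pos"]]
    calls = df.drop(columns=["chrom", "pos"]).astype(float)
    return GenotypeMatrix(snps=snps, calls=calls)


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read haploid-coded homozygous calls from a (plain-text) VCF."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, chroms, poss, ids = [], [], [], []
    for rec in vf:
        calls = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or gt[0] is None:
                calls.append(np.nan)
            else:
                alleles = {a for a in gt if a is not None}
                if len(alleles) != 1:
                    raise ValueError(f"{path}: heterozygous call at {rec.chrom}:{rec.pos}")
                calls.append(float(alleles.pop()))
        rows.append(calls)
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        ids.append(rec.id or f"{rec.chrom}_{rec.pos}")
    snps = pd.DataFrame({"chrom": chroms, "pos": poss}, index=pd.Index(ids, name="snp"))
    calls = pd.DataFrame(rows, index=snps.index, columns=samples)
    return GenotypeMatrix(snps=snps, calls=calls)


# ---------------------------------------------------------------- gene models

def read_gene_models_gff3(path: str | Path, feature: str = "gene") -> list[GeneModel]:
    """Light GFF3 parser keeping records of the given feature type."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 row")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != feature:
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end < start")
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: record without ID attribute")
            genes.append(GeneModel(gene_id, chrom, start_i, end_i, strand))
    return genes


def read_gene_models_bed(path: str | Path) -> list[GeneModel]:
    """BED (0-based half-open) converted to internal 1-based inclusive."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED row")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "."
            genes.append(GeneModel(name, chrom, start + 1, end, strand))
    return genes


def write_gene_models_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\trootplast\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------- signal cube

def write_signal_cube(cube: SignalCube, path: str | Path) -> None:
    long = cube.data.stack(list(range(3)), future_stack=True).rename("signal").reset_index()
    long.to_csv(path, sep="\t", index=False)
    Path(str(path) + ".json").write_text(
        json.dumps({"reference_accession": cube.reference_accession})
    )


def read_signal_cube(path: str | Path, reference_accession: str | None = None) -> SignalCube:
    long = pd.read_csv(path, sep="\t")
    required = {"probe_set", "element", "accession", "treatment", "replicate", "signal"}
    if not required <= set(long.columns):
        raise ValueError(f"{path}: missing columns {required - set(long.columns)}")
    if reference_accession is None:
        meta = Path(str(path) + ".json")
        if meta.exists():
            reference_accession = json.loads(meta.read_text())["reference_accession"]
        else:
            reference_accession = sorted(long["accession"].unique())[0]
    data = long.pivot_table(
        index=["probe_set", "element"],
        columns=["accession", "treatment", "replicate"],
        values="signal",
    )
    return SignalCube(data=data, reference_accession=reference_accession)


# ----------------------------------------------------------------- flat tables

def write_scan(scan: pd.DataFrame, path: str | Path) -> None:
    scan.to_csv(path, sep="\t", index_label="snp", na_rep="NA")


def read_scan(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="snp", na_values=["NA"])


def write_edges(net: network.ModuleTraitNetwork, path: str | Path) -> None:
    net.edges.to_csv(path, sep="\t", index=False)


def write_candidates(cands: pd.DataFrame, path: str | Path) -> None:
    cands.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


# -------------------------------------------------------------------- pipeline

def manhattan_table(scan: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Plot-ready per-SNP table: cumulative coordinate, chromosome colour
    index and the raw-p significance line corresponding to the q cutoff."""
    out = scan.dropna(subset=["p"]).copy()
    offset = 0
    xs = np.empty(len(out))
    color = np.empty(len(out), dtype=int)
    for i, (chrom, grp) in enumerate(out.groupby("chrom", sort=False)):
        loc = out.index.get_indexer(grp.index)
        xs[loc] = grp["pos"].to_numpy() + offset
        color[loc] = i % 2
        offset += int(grp["pos"].max()) + 1
    out["x"] = xs
    out["color"] = color
    sig = out["q"] < q_threshold if "q" in out else pd.Series(False, index=out.index)
    out["threshold_p"] = out.loc[sig, "p"].max() if sig.any() else np.nan
    return out


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the synthetic end-to-end pipeline, writing stage outputs.

    Stages: simulate -> traits -> gwas -> power -> expression -> network ->
    candidates.  Every stochastic stage derives its seed from the config
    seed and logs it; rerunning with the same config reproduces all
    outputs.  Returns a manifest of produced files and headline numbers.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"seed": seed, "stages": {}, "outputs": {}}

    def stage(name):
        logger.info("stage %s", name)
        t0 = time.time()
        return lambda: manifest["stages"].update({name: round(time.time() - t0, 2)})

    with_expression = int(cfg["n_genes"]) >= 2

    done = stage("simulate")
    gm, gtruth = synthetic.simulate_genotypes(
        cfg["n_accessions"], cfg["n_snps"], cfg["n_subpops"], cfg["divergence"],
        seed=seed,
    )
    # plant the demo effect on a common SNP so the association is detectable
    causal_id = gwas.compute_maf(gm).idxmax()
    causal = [synthetic.CausalSnp(causal_id, 1.5, True)]
    _, table, _ = synthetic.simulate_root_traits(
        gm, causal_snps=causal, n_replicates=cfg["n_replicates"], seed=seed + 1
    )
    write_genotypes(gm, out / "genotypes.tsv")
    write_trait_table(table, out / "traits.tsv")
    if with_expression:
        cube, probe_map, etruth = synthetic.simulate_expression_study(
            cfg["n_genes"], seed=seed + 2
        )
        write_signal_cube(cube, out / "signal_cube.tsv")
    done()

    done = stage("traits")
    deltas = traits.trait_deltas(table)
    scaled_deltas = traits.scale_traits(deltas)
    write_scaled_matrix(scaled_deltas, out / "scaled_deltas.tsv")
    part = traits.cluster_rows(scaled_deltas.values)
    pd.DataFrame({"cluster": part.labels, "silhouette": part.silhouettes}).to_csv(
        out / "accession_clusters.tsv", sep="\t", index_label="accession"
    )
    done()

    done = stage("gwas")
    gm_f = gwas.filter_maf(gm, cfg["maf_threshold"])
    K = gwas.compute_kinship(gm)
    # demo annotation: gene models tiled near SNPs, named after the expression
    # study's genes so the candidate intersection is exercised end to end
    gene_names = (list(probe_map["gene_id"]) if with_expression else None)
    picked = gm.snps.iloc[:: max(len(gm.snps) // 200, 1)][["chrom", "pos"]]
    genes = [
        GeneModel(
            gene_names[i % len(gene_names)] if gene_names else f"G{chrom}_{pos}",
            chrom, max(int(pos) - 2000, 1), int(pos) + 2000,
        )
        for i, (chrom, pos) in enumerate(picked.itertuples(index=False))
    ]
    write_gene_models_gff3(genes, out / "genes.gff3")
    all_windows = []
    for trait_name in cfg["scan_traits"]:
        vec = deltas[trait_name]
        scan = gwas.mixed_model_scan(vec, gm_f, K)
        okp = scan["p"].notna()
        q, pi0 = gwas.qvalues(scan.loc[okp, "p"].to_numpy())
        scan["q"] = np.nan
        scan.loc[okp, "q"] = q
        write_scan(scan, out / f"scan_{trait_name}.tsv")
        manhattan_table(scan, cfg["q_threshold"]).to_csv(
            out / f"manhattan_{trait_name}.tsv", sep="\t", index_label="snp"
        )
        sig = scan[scan["q"] < cfg["q_threshold"]]
        all_windows.extend(
            gwas.assign_windows(sig, genes, cfg["window_half_width"],
                                trait_label=f"{trait_name}:delta")
        )
    groups = gwas.merge_groups(all_windows)
    pd.DataFrame(
        [
            {"group": g.group_id, "chrom": g.chrom, "start": g.start, "end": g.end,
             "snps": ",".join(g.snp_ids), "traits": ";".join(sorted(g.traits)),
             "genes": ",".join(gid for gid, _ in g.genes)}
            for g in groups
        ]
    ).to_csv(out / "snp_groups.tsv", sep="\t", index=False)
    done()

    done = stage("power")
    acc_first_env = table.means.xs("lowN", level="environment")["LRlengthave"].dropna()
    Ksub = K.loc[acc_first_env.index, acc_first_env.index]
    power = gwas.power_simulation(
        acc_first_env, Ksub, maf_grid=tuple(cfg["power_mafs"]),
        reps=cfg["power_reps"], seed=seed + 3,
    )
    power.to_csv(out / "power.tsv", sep="\t", index=False)
    done()

    if not with_expression:
        logger.info("expression inputs absent: expression/network stages skipped")
        cands = pd.DataFrame()
        write_candidates(cands, out / "candidates.tsv")
        manifest["outputs"] = {p.name: p.stat().st_size for p in sorted(out.glob("*.tsv"))}
        manifest["n_snp_groups"] = len(groups)
        manifest["skipped"] = ["expression", "network", "candidates"]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest

    done = stage("expression")
    null = expr_mod.build_rank_null(cube, seed=seed + 4)
    mask = expr_mod.detect_outlier_elements(cube, null, alpha=cfg["outlier_alpha"])
    mask.table.to_csv(out / "outlier_elements.tsv", sep="\t", index=False)
    em = expr_mod.summarize_probesets(cube, mask)
    annotation = probe_map.copy()
    flags = expr_mod.flag_probes(annotation, em, cfg["detection_cutoff"])
    flags.to_csv(out / "probe_flags.tsv", sep="\t", index_label="probe_set")
    analysis = em.values.loc[flags.index[flags["analysis_set"]]]
    effects = expr_mod.anova_classify(analysis, fdr=cfg["expression_fdr"])
    gene_classes = effects.classes.copy()
    gene_classes.insert(0, "gene_id", probe_map["gene_id"].reindex(gene_classes.index))
    gene_classes.to_csv(out / "gene_effects.tsv", sep="\t", index_label="probe_set")
    done()

    done = stage("network")
    profiles = effects.responses
    gene_idx = probe_map["gene_id"].reindex(profiles.index)
    profiles = profiles.set_axis(gene_idx.to_numpy(), axis=0)
    classes_by_gene = pd.Series(
        effects.classes["class"].to_numpy(), index=gene_idx.to_numpy()
    )
    mc = network.major_clusters(
        profiles, cfg["edge_r"], cfg["cluster_null_percentile"],
        n_randomizations=50, seed=seed + 5,
    )
    trait_resp = {}
    for env in ("lowN", "highN"):
        env_means = table.means.xs(env, level="environment")
        trait_resp[f"LRlengthave_{env}"] = env_means["LRlengthave"]
    trait_resp["LRlengthave_delta"] = deltas["LRlengthave"]
    trait_mat = traits.scale_traits(pd.DataFrame(trait_resp)).values
    trait_mat = trait_mat.loc[trait_mat.index.intersection(mc.centroids.columns)]
    if len(mc.centroids) and len(trait_mat) >= 3:
        net = network.module_trait_network(mc, trait_mat, cfg["edge_r"])
        write_edges(net, out / "network_edges.tsv")
        corr = net.correlations
    else:
        logger.info("no major clusters or too few accessions: network skipped")
        corr = pd.DataFrame(index=pd.Index([], dtype=int), columns=list(trait_mat.columns))
    stringent = network.stringent_set(classes_by_gene, mc, corr)
    done()

    done = stage("candidates")
    cands = network.candidate_genes(groups, classes_by_gene, stringent)
    write_candidates(cands, out / "candidates.tsv")
    done()

    manifest["outputs"] = {p.name: p.stat().st_size for p in sorted(out.glob("*.tsv"))}
    manifest["n_snp_groups"] = len(groups)
    manifest["n_candidates"] = int(len(cands))
    manifest["stringent_set_size"] = len(stringent)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
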