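"""Readers and writers for the on-disk formats.

* genotypes: VCF (unphased GT, missing "./.") via cyvcf2, or a 0/1/2
  dosage CSV (samples x SNPs, empty cell = missing);
* GWAS summary statistics: whitespace-delimited PLINK association dialect
  with header ``SNP A1 BETA SE P N``;
* cohort: a directory of CSVs (clinical, cognitive, methylation,
  probe_meta, labels) + genotypes.vcf + truth.json;
* LD blocks: TSV triplets (i, j, r) per block;
* graphs: weighted edge-list TSV + JSON provenance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Cohort, CohortConfig, CohortTruth

logger = logging.getLogger("adgcn_omics")

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_summary_stats",
    "read_summary_stats",
    "write_cohort",
    "read_cohort",
    "write_ld_blocks",
    "read_ld_blocks",
    "write_graph",
]

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)
_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path, genotypes, snp_ids, sample_ids) -> None:
    """Write dosages as an unphased biallelic VCF (ALT is the counted
    allele; NaN dosage becomes ./.)."""
    G = np.asarray(genotypes, dtype=float)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j, snp in enumerate(snp_ids):
            calls = [
                "./." if np.isnan(G[i, j]) else _GT[int(G[i, j])]
                for i in range(G.shape[0])
            ]
            fh.write(f"1\t{j + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_vcf(path):
    """Read a VCF into (dosage matrix n x m with NaN for missing, snp ids,
    sample ids). Dosage counts the ALT allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, cols = [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types, dtype=float)
        col = np.where(gt == 0, 0.0,
                       np.where(gt == 1, 1.0,
                                np.where(gt == 3, 2.0, np.nan)))
        cols.append(col)
    vcf.close()
    G = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return G, ids, samples


def write_summary_stats(path, stats: pd.DataFrame) -> None:
    stats.to_csv(path, sep=" ", index=False,
                 columns=["SNP", "A1", "BETA", "SE", "P", "N"])


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    missing = {"SNP", "A1", "BETA", "SE", "P", "N"} - set(df.columns)
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    return df


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Persist a cohort as a directory of plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    idx = pd.Index(cohort.sample_ids, name="sample_id")
    cohort.clinical.set_axis(idx).to_csv(out / "clinical.csv")
    pd.DataFrame(cohort.cognitive, index=idx,
                 columns=[f"cog{i}" for i in range(cohort.cognitive.shape[1])]
                 ).to_csv(out / "cognitive.csv")
    pd.DataFrame(cohort.methylation, index=idx, columns=cohort.probe_ids
                 ).to_csv(out / "methylation.csv")
    cohort.probe_meta.to_csv(out / "probe_meta.csv", index=False)
    pd.Series(cohort.labels, index=idx, name="label").to_csv(out / "labels.csv")
    write_vcf(out / "genotypes.vcf", cohort.genotypes, cohort.snp_ids,
              cohort.sample_ids)
    pd.Series(cohort.ld_block_index, name="block").to_csv(
        out / "ld_blocks.csv", index_label="snp_index")
    with open(out / "truth.json", "w") as fh:
        json.dump({"truth": cohort.truth.to_dict(),
                   "config": cohort.config.to_dict()}, fh, indent=1)
    logger.info("wrote cohort (%d samples) to %s", cohort.n_samples, out)


def read_cohort(in_dir) -> Cohort:
    src = Path(in_dir)
    clinical = pd.read_csv(src / "clinical.csv", index_col=0)
    cognitive = pd.read_csv(src / "cognitive.csv", index_col=0)
    methylation = pd.read_csv(src / "methylation.csv", index_col=0)
    probe_meta = pd.read_csv(src / "probe_meta.csv")
    labels = pd.read_csv(src / "labels.csv", index_col=0)["label"]
    G, snp_ids, sample_ids = read_vcf(src / "genotypes.vcf")
    blocks = pd.read_csv(src / "ld_blocks.csv", index_col=0)["block"]
    with open(src / "truth.json") as fh:
        meta = json.load(fh)
    t = meta["truth"]
    truth = CohortTruth(
        causal_snp_indices=np.array(t["causal_snp_indices"], dtype=int),
        causal_snp_effects=np.array(t["causal_snp_effects"], dtype=float),
        informative_probe_indices=np.array(t["informative_probe_indices"],
                                           dtype=int),
        informative_probe_shifts=np.array(t["informative_probe_shifts"],
                                          dtype=float),
    )
    cfg = meta["config"]
    cfg["maf_range"] = tuple(cfg["maf_range"])
    if sample_ids != list(clinical.index):
        raise ValueError("VCF and clinical.csv sample order disagree")
    return Cohort(
        sample_ids=sample_ids,
        labels=labels.to_numpy(int),
        clinical=clinical.reset_index(drop=True),
        cognitive=cognitive.to_numpy(float),
        genotypes=G,
        snp_ids=snp_ids,
        ld_block_index=blocks.to_numpy(int),
        methylation=methylation.to_numpy(float),
        probe_ids=list(methylation.columns),
        probe_meta=probe_meta,
        truth=truth,
        config=CohortConfig(**cfg),
    )


def write_ld_blocks(path, ld) -> None:
    """LD blocks as TSV triplets (block, i, j, r) with panel indices."""
    with open(path, "w") as fh:
        fh.write("block\ti\tj\tr\n")
        for b, mat in ld.matrices.items():
            idx = ld.snps_in(b)
            for a in range(len(idx)):
                for c in range(a, len(idx)):
                    fh.write(f"{b}\t{idx[a]}\t{idx[c]}\t{mat[a, c]:.6g}\n")


def read_ld_blocks(path):
    from .prs import LdBlocks

    df = pd.read_csv(path, sep="\t")
    n = int(max(df["i"].max(), df["j"].max())) + 1
    block_index = np.zeros(n, dtype=int)
    for _, row in df.iterrows():
        block_index[int(row["i"])] = int(row["block"])
        block_index[int(row["j"])] = int(row["block"])
    mats = {}
    for b in sorted(df["block"].unique()):
        idx = np.where(block_index == b)[0]
        pos = {int(j): a for a, j in enumerate(idx)}
        mat = np.zeros((len(idx), len(idx)))
        for _, row in df[df["block"] == b].iterrows():
            a, c = pos[int(row["i"])], pos[int(row["j"])]
            mat[a, c] = mat[c, a] = row["r"]
        mats[int(b)] = mat
    return LdBlocks(block_index=block_index, matrices=mats)


def write_graph(graph, edge_path, provenance_path=None) -> None:
    """Weighted edge-list TSV plus JSON provenance."""
    with open(edge_path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for (i, j) in graph.edges:
            fh.write(f"{i}\t{j}\t{graph.weights.get((i, j), 1.0):.6g}\n")
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            json.dump({"n_nodes": graph.n_nodes, "strategy": graph.strategy,
                       "sim_threshold": graph.sim_threshold, "k": graph.k,
                       "n_edges": len(graph.edges),
                       "provenance": graph.provenance}, fh, indent=1)
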