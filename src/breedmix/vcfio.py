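"""VCF and table I/O.

Genotypes exchange as VCFv4.2 with a GT-only FORMAT: diploid unphased
calls, ``./.`` (or any half-call) read as missing, multi-allelic records
skipped with a logged count. Reading uses cyvcf2; writing is a direct
text emitter since only GT is carried.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def read_genotypes_vcf(path, samples: list[str] | None = None) -> GenotypeMatrix:
    """Parse a VCF into a dosage matrix (count of alt alleles).

    ``./.`` and half-calls become missing; multi-allelic records are
    skipped (count logged); phase is ignored. ``samples`` optionally
    restricts and orders the sample columns.
    """
    vcf = VCF(str(path), samples=samples, gts012=False)
    got = list(vcf.samples)
    if samples is not None and set(got) != set(samples):
        missing = sorted(set(samples) - set(got))
        raise KeyError(f"samples absent from VCF: {missing}")

    rows = []
    meta = {"chrom": [], "pos": [], "id": [], "ref": [], "alt": []}
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        gts = variant.genotypes  # [[a0, a1, phased], ...]
        dos = np.empty(len(got))
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                dos[i] = np.nan
            else:
                dos[i] = float(sum(alleles))
        rows.append(dos)
        meta["chrom"].append(variant.CHROM)
        meta["pos"].append(variant.POS)
        meta["id"].append(
            variant.ID
            if variant.ID not in (None, ".")
            else f"{variant.CHROM}:{variant.POS}:{variant.REF}:{variant.ALT[0]}"
        )
        meta["ref"].append(variant.REF)
        meta["alt"].append(variant.ALT[0])
    vcf.close()
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)

    sites = pd.DataFrame(meta)
    dosages = (
        np.asarray(rows).T if rows else np.empty((len(got), 0))
    )
    return GenotypeMatrix(dosages, got, sites)


def write_genotypes_vcf(G: GenotypeMatrix, path) -> None:
    """Write a GT-only VCFv4.2 file (unphased, ``./.`` for missing)."""
    contigs = list(dict.fromkeys(G.sites["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=breedmix\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            max_pos = int(G.sites.loc[G.sites["chrom"] == c, "pos"].max())
            fh.write(f"##contig=<ID={c},length={max_pos + 1}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(G.samples)) + "\n")
        for m in range(G.n_sites):
            site = G.sites.iloc[m]
            gts = [
                _GT_STRINGS.get(d, "./.") if not np.isnan(d) else "./."
                for d in G.dosages[:, m]
            ]
            fh.write(
                "\t".join(
                    [
                        str(site["chrom"]),
                        str(int(site["pos"])),
                        str(site["id"]),
                        str(site["ref"]),
                        str(site["alt"]),
                        ".",
                        ".",
                        ".",
                        "GT",
                    ]
                    + gts
                )
                + "\n"
            )


def read_site_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="sample", float_format="%.6f")


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")
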