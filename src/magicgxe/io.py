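"""Readers and writers for the pipeline's on-disk formats.

Phenotypes travel as long-format TSV (line, environment, plot, x, y,
trait_1..trait_t); genotypes as a 0/2 allele-count TSV matrix or a minimal
VCF with homozygous GT calls; the marker map as TSV (marker, chrom, pos);
founder probabilities as an HDF5 dataset (marker x line x founder) or a
long TSV; kinship as TSV with line-id headers.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .genotypes import KinshipMatrix
from .simulate import DHPopulation, FounderPanel

__all__ = [
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_marker_map_tsv",
    "read_marker_map_tsv",
    "write_vcf",
    "read_vcf",
    "write_founder_probs_h5",
    "read_founder_probs_h5",
    "write_founder_probs_tsv",
    "write_kinship_tsv",
    "read_kinship_tsv",
]


def write_phenotypes_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotypes_tsv(pop: DHPopulation, path) -> None:
    mm = pop.panel.marker_map()
    df = pd.DataFrame(pop.genotypes.T, columns=pop.lines)
    pd.concat([mm, df], axis=1).to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path):
    df = pd.read_csv(path, sep="\t")
    mm = df[["marker", "chrom", "pos"]]
    geno = df.drop(columns=["marker", "chrom", "pos"]).to_numpy().T
    lines = [c for c in df.columns if c not in ("marker", "chrom", "pos")]
    return geno, mm, lines


def write_marker_map_tsv(panel_or_map, path) -> None:
    mm = panel_or_map.marker_map() if isinstance(panel_or_map, FounderPanel) else panel_or_map
    mm.to_csv(path, sep="\t", index=False)


def read_marker_map_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(pop: DHPopulation, path) -> None:
    """Minimal VCF 4.2 with homozygous GT calls (0/0 or 1/1) for DH lines."""
    mm = pop.panel.marker_map()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pop.panel.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(pop.lines) + "\n")
        for j in range(pop.panel.n_markers):
            calls = "\t".join("1/1" if g == 2 else "0/0" for g in pop.genotypes[:, j])
            fh.write(
                f"{mm['chrom'].iloc[j]}\t{mm['pos'].iloc[j]}\t{mm['marker'].iloc[j]}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path):
    """Read a homozygous-GT VCF into (allele-count matrix, marker map, lines).

    Uses cyvcf2 when available, else a plain-text parser (the files written
    by :func:`write_vcf` are simple enough for either).
    """
    try:
        from cyvcf2 import VCF

        v = VCF(str(path))
        lines = list(v.samples)
        rows, chroms, poss, ids = [], [], [], []
        for rec in v:
            gt = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown/hom-alt depending; use genotypes
            counts = [a[0] + a[1] for a in rec.genotypes]
            rows.append(counts)
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            ids.append(rec.ID)
        geno = np.array(rows).T
    except ImportError:
        lines, rows, chroms, poss, ids = None, [], [], [], []
        with open(path) as fh:
            for ln in fh:
                if ln.startswith("##"):
                    continue
                if ln.startswith("#CHROM"):
                    lines = ln.rstrip("\n").split("\t")[9:]
                    continue
                parts = ln.rstrip("\n").split("\t")
                chroms.append(parts[0])
                poss.append(int(parts[1]))
                ids.append(parts[2])
                rows.append([sum(int(x) for x in p.replace("|", "/").split("/")) for p in parts[9:]])
        geno = np.array(rows).T
    mm = pd.DataFrame({"marker": ids, "chrom": chroms, "pos": poss})
    # chromosome ids are written as integers when possible
    try:
        mm["chrom"] = mm["chrom"].astype(int)
    except (ValueError, TypeError):
        pass
    return geno, mm, lines


def write_founder_probs_h5(pop: DHPopulation, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("founder_probs", data=pop.founder_probs, compression="gzip")
        f.create_dataset("lines", data=np.array(pop.lines, dtype="S"))
        mm = pop.panel.marker_map()
        f.create_dataset("markers", data=np.array(mm["marker"], dtype="S"))
        f.create_dataset("chrom", data=np.array(mm["chrom"].astype(str), dtype="S"))
        f.create_dataset("pos", data=mm["pos"].to_numpy())


def read_founder_probs_h5(path):
    with h5py.File(path, "r") as f:
        probs = f["founder_probs"][...]
        lines = [s.decode() for s in f["lines"][...]]
        mm = pd.DataFrame(
            {
                "marker": [s.decode() for s in f["markers"][...]],
                "chrom": [s.decode() for s in f["chrom"][...]],
                "pos": f["pos"][...],
            }
        )
    try:
        mm["chrom"] = mm["chrom"].astype(int)
    except (ValueError, TypeError):
        pass
    return probs, mm, lines


def write_founder_probs_tsv(pop: DHPopulation, path) -> None:
    """Long-format TSV: marker, line, founder, probability (nonzero entries)."""
    mm = pop.panel.marker_map()
    m, r, nf = pop.founder_probs.shape
    mi, li, fi = np.nonzero(pop.founder_probs > 0)
    df = pd.DataFrame(
        {
            "marker": mm["marker"].to_numpy()[mi],
            "line": np.array(pop.lines)[li],
            "founder": fi,
            "probability": pop.founder_probs[mi, li, fi],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_kinship_tsv(k: KinshipMatrix, path) -> None:
    pd.DataFrame(k.values, index=k.lines, columns=k.lines).to_csv(path, sep="\t")


def read_kinship_tsv(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(values=df.to_numpy(), lines=list(df.columns))
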