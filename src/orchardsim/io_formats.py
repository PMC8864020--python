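"""Plain-text writers/readers: PLINK .ped/.map, VCF 4.2, pedigree files,
phenotype/EBV tables, relationship matrices and run manifests.

All tabular outputs are comma-separated UTF-8 with '.' decimals; every
writer has a matching reader so formats round-trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simpop import GeneticMap, Pedigree, Population

__all__ = [
    "locus_names",
    "write_plink", "read_plink",
    "write_vcf",
    "write_pedigree", "read_pedigree",
    "write_phenotypes", "read_phenotypes",
    "write_ebv_table",
    "write_matrix", "read_matrix",
    "write_manifest", "read_manifest",
]


def locus_names(gmap: GeneticMap) -> list[str]:
    """Stable locus identifiers: chr<1-based>_<1-based locus rank>."""
    names, count = [], {}
    for c in gmap.chrom:
        count[c] = count.get(c, 0) + 1
        names.append(f"chr{c + 1}_{count[c]}")
    return names


def _bp(pos_cM: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(pos_cM) * 1e4).astype(int)


def write_plink(pop: Population, prefix: str | Path, loci: np.ndarray | None = None) -> None:
    """PLINK .ped/.map pair; alleles '1'/'2', dosage counts allele '2'.

    ``loci`` optionally restricts output to a locus-index subset (e.g. the
    marker panel).  Map positions are written 1-based in bp as cM * 1e4.
    """
    prefix = Path(prefix)
    gmap = pop.gmap
    idx = np.arange(gmap.n_loci) if loci is None else np.asarray(loci)
    all_names = locus_names(gmap)
    names = [all_names[i] for i in idx]

    with open(prefix.with_suffix(".map"), "w") as fh:
        for i, name in zip(idx, names):
            fh.write(f"{gmap.chrom[i] + 1} {name} {gmap.pos_cM[i]:.6f} {_bp(gmap.pos_cM[i:i+1])[0]}\n")

    alleles = {0: "1 1", 1: "1 2", 2: "2 2"}
    ped = pop.pedigree
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for row in range(ped.n):
            fam = pop.family[row]
            fid = f"F{fam + 1}" if fam >= 0 else "FOUNDER"
            geno = " ".join(alleles[int(g)] for g in pop.genotypes[row, idx])
            fh.write(f"{fid} {ped.ids[row]} {ped.sire[row]} {ped.dam[row]} 0 -9 {geno}\n")


def read_plink(prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Read a .ped/.map pair back to (samples, map, dosage matrix)."""
    prefix = Path(prefix)
    map_df = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                         names=["chrom", "id", "cM", "bp"])
    rows, dosages = [], []
    for line in Path(prefix.with_suffix(".ped")).read_text().splitlines():
        parts = line.split()
        rows.append(dict(fid=parts[0], iid=int(parts[1]), sire=int(parts[2]),
                         dam=int(parts[3])))
        al = np.array(parts[6:], dtype=int)
        dosages.append((al.reshape(-1, 2) == 2).sum(axis=1))
    return pd.DataFrame(rows), map_df, np.array(dosages, dtype=np.int8)


def write_vcf(pop: Population, path: str | Path, loci: np.ndarray | None = None) -> None:
    """Minimal VCF 4.2 export with unphased GT genotypes (REF=A, ALT=T)."""
    gmap = pop.gmap
    idx = np.arange(gmap.n_loci) if loci is None else np.asarray(loci)
    names = locus_names(gmap)
    gts = {0: "0/0", 1: "0/1", 2: "1/1"}
    samples = [str(i) for i in pop.pedigree.ids]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=orchardsim\n")
        for c in range(gmap.n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1},length={int(gmap.chrom_length * 1e4) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        bp = _bp(gmap.pos_cM)
        for i in idx:
            cols = "\t".join(gts[int(g)] for g in pop.genotypes[:, i])
            fh.write(f"chr{gmap.chrom[i] + 1}\t{bp[i]}\t{names[i]}\tA\tT\t.\tPASS\t.\tGT\t{cols}\n")


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """3-column whitespace pedigree (id, sire, dam; 0 = unknown)."""
    with open(path, "w") as fh:
        for i, s, d in zip(ped.ids, ped.sire, ped.dam):
            fh.write(f"{i} {s} {d}\n")


def read_pedigree(path: str | Path) -> Pedigree:
    arr = np.loadtxt(path, dtype=int, ndmin=2)
    return Pedigree(arr[:, 0], arr[:, 1], arr[:, 2])


def write_phenotypes(path: str | Path, ids: np.ndarray, family: np.ndarray,
                     tbv: np.ndarray, phenotype: np.ndarray, n_ramets: int) -> None:
    pd.DataFrame({
        "id": ids, "family": family, "tbv": tbv,
        "phenotype": phenotype, "n_ramets": n_ramets,
    }).to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ebv_table(path: str | Path, ids: np.ndarray, family: np.ndarray,
                    method: str, ebv: np.ndarray, tbv: np.ndarray | None = None) -> None:
    df = pd.DataFrame({"id": ids, "family": family, "method": method, "ebv": ebv})
    if tbv is not None:
        df["tbv"] = tbv
    df.to_csv(path, index=False)


def write_matrix(path: str | Path, values: np.ndarray, ids: np.ndarray,
                 long_format: bool = False) -> None:
    """Whitespace-delimited full matrix with a header id row, or an (i, j,
    value) three-column long file."""
    ids = [str(i) for i in ids]
    if long_format:
        with open(path, "w") as fh:
            for i in range(len(ids)):
                for j in range(len(ids)):
                    fh.write(f"{ids[i]} {ids[j]} {values[i, j]:.10g}\n")
        return
    with open(path, "w") as fh:
        fh.write(" ".join(ids) + "\n")
        for row in values:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    lines = Path(path).read_text().splitlines()
    ids = np.array(lines[0].split())
    vals = np.array([[float(x) for x in line.split()] for line in lines[1:]])
    return vals, ids


def write_manifest(path: str | Path, entries: dict) -> None:
    """Flat key=value run manifest, one entry per line."""
    with open(path, "w") as fh:
        for k, v in entries.items():
            fh.write(f"{k}={v}\n")


def read_manifest(path: str | Path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            k, _, v = line.partition("=")
            out[k] = v
    return out
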