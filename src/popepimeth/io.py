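"""Readers and writers for the plain-text formats the pipeline consumes.

Conventions
-----------
Internal tables are 1-based, inclusive coordinates (VCF style).  BED and
narrowPeak files are 0-based half-open on disk; the converters here do the
shift in both directions.  Methylation matrices are TSV with probes in rows
and a header row of sample ids.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_methylation_tsv",
    "write_methylation_tsv",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gmt",
    "write_gmt",
    "read_jaspar_pwms",
    "write_jaspar_pwms",
    "read_vcf_genotypes",
    "write_vcf",
]


# ---------------------------------------------------------------------------
# methylation matrices / generic tables


def read_methylation_tsv(path: str) -> pd.DataFrame:
    """Probes x samples matrix; first column holds probe ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_methylation_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="probe")


# ---------------------------------------------------------------------------
# BED / narrowPeak


def read_bed(path: str) -> pd.DataFrame:
    """Return intervals with 1-based inclusive ``start``/``end`` columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based incl.
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    """``df`` has 1-based inclusive start/end; written 0-based half-open."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int) - 1,
            "end": df["end"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


_NARROWPEAK_COLS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "signalValue",
    "pValue",
    "qValue",
    "peak",
]


def read_narrowpeak(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=_NARROWPEAK_COLS)
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


def write_narrowpeak(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    for col in _NARROWPEAK_COLS:
        if col not in out.columns:
            out[col] = {"name": ".", "strand": "."}.get(col, 0)
    out = out[_NARROWPEAK_COLS]
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# JASPAR PWMs


def read_jaspar_pwms(path: str) -> dict[str, np.ndarray]:
    """Parse JASPAR 2016-style text: ``>ID NAME`` then four ``A [ ... ]`` rows.

    Returns count matrices of shape (4, L) in A, C, G, T order.
    """
    pwms: dict[str, np.ndarray] = {}
    name = None
    rows: dict[str, list[float]] = {}
    order = ["A", "C", "G", "T"]

    def flush():
        if name is not None and len(rows) == 4:
            pwms[name] = np.array([rows[b] for b in order], dtype=float)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                rows = {}
            else:
                base, rest = line.split(None, 1)
                rest = rest.strip().lstrip("[").rstrip("]")
                rows[base] = [float(x) for x in rest.split()]
    flush()
    return pwms


def write_jaspar_pwms(pwms: Mapping[str, np.ndarray], path: str) -> None:
    with open(path, "w") as fh:
        for name, mat in pwms.items():
            fh.write(f">{name} {name}\n")
            for base, row in zip("ACGT", np.asarray(mat)):
                vals = " ".join(f"{v:.0f}" if float(v).is_integer() else f"{v:g}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf_genotypes(path: str):
    """Read a VCF into (snp annotation DataFrame, dosage matrix, haplotypes).

    Dosages are samples x SNPs in {0,1,2}; haplotypes are (2*samples) x SNPs
    with sample i occupying rows 2i and 2i+1.  The ancestral allele is taken
    from the INFO AA field when present, else the REF allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    ids, chroms, positions, refs, alts, aas = [], [], [], [], [], []
    dosage_rows, hap_rows = [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        aas.append(var.INFO.get("AA") or var.REF)
        gts = np.array(var.genotypes)  # (n, 3): allele1, allele2, phased
        hap_rows.append(gts[:, :2].reshape(-1))
        dosage_rows.append(gts[:, 0] + gts[:, 1])
    annot = pd.DataFrame(
        {
            "snp": ids,
            "chrom": chroms,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "ancestral": aas,
        }
    ).set_index("snp")
    dosages = np.array(dosage_rows, dtype=np.int8).T if dosage_rows else np.zeros((len(samples), 0), np.int8)
    haps = np.array(hap_rows, dtype=np.int8).T if hap_rows else np.zeros((2 * len(samples), 0), np.int8)
    return annot, dosages, haps, samples


def write_vcf(
    path: str,
    snp_annot: pd.DataFrame,
    haplotypes: np.ndarray,
    samples: Sequence[str],
) -> None:
    """Write phased haplotypes ((2n) x SNPs, sample i in rows 2i, 2i+1)."""
    haps = np.asarray(haplotypes)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in _contigs_from_annot(snp_annot):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, (snp, row) in enumerate(snp_annot.iterrows()):
            gts = "\t".join(
                f"{haps[2 * i, j]}|{haps[2 * i + 1, j]}" for i in range(len(samples))
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row['ref']}\t{row['alt']}\t.\tPASS\t"
                f"AA={row['ancestral']}\tGT\t{gts}\n"
            )


def _contigs_from_annot(snp_annot: pd.DataFrame) -> Iterable[tuple[str, int]]:
    for chrom, grp in snp_annot.groupby("chrom", sort=True):
        yield str(chrom), int(grp["pos"].max()) + 1000
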