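"""File interchange for the pipeline.

Summary statistics travel as (optionally gzipped) tab-delimited tables with a
fixed header; genotype panels as VCF; gene intervals as BED (0-based,
half-open); gene sets as GMT; truth labels and model files as JSON sidecars.
All genomic coordinates are 1-based inclusive internally and converted at the
BED boundary only.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: external summary-statistics header -> internal column names
SUMSTATS_COLUMNS = {
    "SNP": "variant_id",
    "CHR": "chrom",
    "BP": "pos",
    "EA": "ea",
    "OA": "oa",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "p",
    "N": "n",
    "INFO": "info",
    "CASE_FRAC": "case_frac",
}
_INTERNAL_TO_EXTERNAL = {v: k for k, v in SUMSTATS_COLUMNS.items()}


def write_sumstats(table: pd.DataFrame, path: str | Path) -> None:
    """Write an association table in the fixed-header TSV dialect.

    Columns beyond the fixed header (Q, TAU2, DIRECTION, P_SEXHET, ...) are
    appended verbatim in upper case. Paths ending in ``.gz`` are gzipped.
    """
    out = table.rename(columns=_INTERNAL_TO_EXTERNAL)
    fixed = [c for c in SUMSTATS_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in SUMSTATS_COLUMNS]
    out = out[fixed + extra]
    out.columns = [c.upper() for c in out.columns]
    out.to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read the fixed-header TSV dialect back into internal column names."""
    table = pd.read_csv(path, sep="\t")
    rename = {c: SUMSTATS_COLUMNS.get(c, c.lower()) for c in table.columns}
    table = table.rename(columns=rename)
    table["chrom"] = table["chrom"].astype(str)
    return table


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write gene intervals as BED: expects columns chrom, start, end, name
    with 1-based inclusive start/end; converts to 0-based half-open."""
    out = intervals[["chrom", "start", "end", "name"]].copy()
    out["start"] = out["start"].astype(int) - 1
    with open(path, "w") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED into 1-based inclusive chrom/start/end/name."""
    table = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
    )
    table["chrom"] = table["chrom"].astype(str)
    table["start"] = table["start"].astype(int) + 1
    return table


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_ld_matrix(r2: np.ndarray, variant_ids: list[str], path: str | Path) -> None:
    pd.DataFrame(r2, index=variant_ids, columns=variant_ids).to_csv(path, sep="\t")


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


# ---------------------------------------------------------------------------
# VCF panel interchange

def write_panel_vcf(panel, path: str | Path, phased: bool = True) -> None:
    """Write a haplotype panel as an uncompressed VCF with GT fields.

    Haplotype pairs (2i, 2i+1) form sample i; ``|`` separators are used when
    phase is meaningful, ``/`` otherwise.
    """
    n_samples = panel.haplotypes.shape[0] // 2
    sep = "|" if phased else "/"
    samples = [f"S{i}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        H = panel.haplotypes
        for j, vid in enumerate(panel.variant_ids):
            a = H[0::2, j]
            b = H[1::2, j]
            gts = [f"{x}{sep}{y}" for x, y in zip(a, b)]
            fh.write("\t".join([
                str(panel.chrom[j]), str(panel.positions[j]), vid,
                panel.oa[j], panel.ea[j], ".", "PASS", ".", "GT", *gts,
            ]) + "\n")


def read_panel_vcf(path: str | Path):
    """Read a VCF written by :func:`write_panel_vcf` back into a panel."""
    from .synthetic import HaplotypePanel

    chroms, positions, ids, ea, oa, rows = [], [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chroms.append(f[0])
            positions.append(int(f[1]))
            ids.append(f[2])
            oa.append(f[3])
            ea.append(f[4])
            alleles = []
            for gt in f[9:]:
                a, b = gt.replace("|", "/").split("/")
                alleles.extend([int(a), int(b)])
            rows.append(alleles)
    haplotypes = np.array(rows, dtype=np.uint8).T
    m = len(ids)
    return HaplotypePanel(
        variant_ids=ids,
        chrom=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ea=ea, oa=oa,
        haplotypes=haplotypes,
        block_map=np.zeros(m, dtype=np.int64),
        eaf=haplotypes.mean(axis=0),
    )
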