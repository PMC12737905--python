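"""Plain-text readers and writers for the pipeline's tables.

All genomic tables use 1-based positions except the composition
BED-like table, which is 0-based half-open (the sole 0-based file).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .arraydosage import DosageCallMatrix
from .simulate import CompositionMap, MarkerSignalTable


def write_ab_sites(sites: pd.DataFrame, path: str | Path) -> None:
    sites[["chrom_set", "pos", "a_allele", "b_allele"]].to_csv(
        path, sep="\t", index=False
    )


def read_ab_sites(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom_set": str})


def write_composition(cmap: CompositionMap, path: str | Path) -> None:
    cmap.to_frame().to_csv(path, sep="\t", index=False)


def read_composition(path: str | Path) -> CompositionMap:
    return CompositionMap.from_frame(
        pd.read_csv(path, sep="\t", dtype={"chrom_set": str})
    )


def write_pedigree(pedigree: pd.DataFrame, path: str | Path) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_pileups(path: str | Path) -> pd.DataFrame:
    """Long pileup table: chrom_set, pos, source, allele, count."""
    return pd.read_csv(path, sep="\t", dtype={"chrom_set": str, "allele": str})


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Per-site counts: sample, chrom_set, pos, a_count, b_count."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom_set": str})
    if "missing" not in df.columns:
        df["missing"] = (df["a_count"] + df["b_count"]) == 0
    return df


def write_allele_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def write_signal_table(table: MarkerSignalTable, prefix: str | Path) -> None:
    """Write a MarkerSignalTable as <prefix>.ratios.csv / .markers.csv / .roles.csv."""
    prefix = str(prefix)
    table.ratios.to_csv(prefix + ".ratios.csv")
    table.markers.to_csv(prefix + ".markers.csv")
    pd.Series(table.roles, name="role").rename_axis("sample").to_csv(
        prefix + ".roles.csv"
    )


def read_signal_table(prefix: str | Path) -> MarkerSignalTable:
    prefix = str(prefix)
    ratios = pd.read_csv(prefix + ".ratios.csv", index_col=0)
    markers = pd.read_csv(prefix + ".markers.csv", index_col=0)
    roles = pd.read_csv(prefix + ".roles.csv", index_col=0)["role"].to_dict()
    return MarkerSignalTable(markers=markers, ratios=ratios, roles=roles)


def write_call_matrix(matrix: DosageCallMatrix, prefix: str | Path) -> None:
    """Write a DosageCallMatrix as <prefix>.calls.csv / .roles.csv [/ .markers.csv]."""
    prefix = str(prefix)
    matrix.calls.to_csv(prefix + ".calls.csv")
    pd.Series(matrix.roles, name="role").rename_axis("sample").to_csv(
        prefix + ".roles.csv"
    )
    if matrix.markers is not None:
        matrix.markers.to_csv(prefix + ".markers.csv")


def read_call_matrix(prefix: str | Path) -> DosageCallMatrix:
    """Read a raw dosage-call matrix (markers x samples) plus sample roles.

    This is the ingestion path for externally scored call tables laid
    out marker-per-row, sample-per-column with a companion sample-role
    table.
    """
    prefix = str(prefix)
    calls = pd.read_csv(prefix + ".calls.csv", index_col=0)
    roles = pd.read_csv(prefix + ".roles.csv", index_col=0)["role"].to_dict()
    markers = None
    if Path(prefix + ".markers.csv").exists():
        markers = pd.read_csv(prefix + ".markers.csv", index_col=0)
    return DosageCallMatrix(calls=calls, roles=roles, markers=markers)
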