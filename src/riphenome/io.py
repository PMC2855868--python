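"""Readers and writers for the panel's plain-text interchange formats.

* ``.geno`` -- GeneNetwork-style genotype dialect: ``@key: value`` header
  lines, then a tab-delimited table with columns ``Chr, Locus, cM, Mb``
  followed by one column per strain, calls coded ``B/D/H/U``.
* trait CSV -- one row per animal per trait (long format).
* BED -- gene annotations, 0-based half-open bp coordinates, converted to
  megabases internally.
* GMT -- gene sets: name, description, then tab-separated gene ids.
* expression TSV -- ``probe_id, gene_id`` then one column per strain.

All writers accept an optional provenance ``header`` mapping emitted as
``#key: value`` comment lines; readers skip such lines.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .types import (ExpressionMatrix, GENOTYPE_CODES, GenotypeMatrix,
                    validate_phenotypes)

__all__ = [
    "read_geno", "write_geno", "read_traits", "write_traits",
    "read_bed", "write_bed", "read_gmt", "write_gmt",
    "read_expression", "write_expression",
    "read_strain_matrix", "write_strain_matrix",
]


def _header_lines(header: Mapping[str, object] | None) -> list[str]:
    return [f"#{k}: {v}" for k, v in (header or {}).items()]


def read_geno(path: str | Path) -> GenotypeMatrix:
    """Parse a GeneNetwork-style .geno file."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    columns: list[str] | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("@"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                continue
            fields = line.split("\t")
            if columns is None:
                columns = fields
                if columns[:4] != ["Chr", "Locus", "cM", "Mb"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header starting "
                        f"'Chr\\tLocus\\tcM\\tMb', got {columns[:4]}")
                dup = pd.Index(columns[4:])
                if dup.duplicated().any():
                    raise ValueError(
                        f"{path}:{lineno}: duplicated strain columns "
                        f"{sorted(dup[dup.duplicated()])}")
                continue
            if len(fields) != len(columns):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(columns)} fields, got {len(fields)}")
            for call in fields[4:]:
                if call not in GENOTYPE_CODES:
                    raise ValueError(f"{path}:{lineno}: unknown genotype "
                                     f"code {call!r}")
            rows.append(fields)
    if columns is None or not rows:
        raise ValueError(f"{path}: no genotype rows found")
    strains = columns[4:]
    mmap = pd.DataFrame(
        {"marker": [r[1] for r in rows], "chrom": [r[0] for r in rows],
         "cM": [float(r[2]) for r in rows], "Mb": [float(r[3]) for r in rows]})
    calls = pd.DataFrame(np.array([r[4:] for r in rows]).T, index=strains,
                         columns=mmap["marker"])
    subpop = meta.get("subpopulations", "")
    if subpop:
        mapping = dict(item.split("=") for item in subpop.split(";") if item)
        labels = pd.Series({s: mapping.get(s, "unknown") for s in strains})
    else:
        labels = pd.Series("panel", index=strains)
    return GenotypeMatrix(calls=calls, marker_map=mmap,
                          subpopulation=labels.rename("subpopulation"))


def write_geno(genotypes: GenotypeMatrix, path: str | Path,
               name: str = "synthetic",
               header: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    sub = ";".join(f"{s}={g}" for s, g in genotypes.subpopulation.items())
    lines = _header_lines(header)
    lines += [f"@name: {name}", "@type: riset", f"@subpopulations: {sub}"]
    strains = genotypes.strains
    lines.append("\t".join(["Chr", "Locus", "cM", "Mb"] + strains))
    calls = genotypes.calls
    for _, m in genotypes.marker_map.iterrows():
        row = [str(m["chrom"]), m["marker"], f"{m['cM']:g}", f"{m['Mb']:g}"]
        row += calls[m["marker"]].tolist()
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a long-format animal-level trait CSV."""
    data = pd.read_csv(path, comment="#",
                       dtype={"animal": str, "strain": str, "sex": str,
                              "battery": str, "trait": str})
    return validate_phenotypes(data)


def write_traits(data: pd.DataFrame, path: str | Path,
                 header: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(header):
            fh.write(line + "\n")
        data.to_csv(fh, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read gene annotations from BED (0-based half-open bp -> Mb)."""
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs at least "
                                 f"4 fields, got {len(fields)}")
            chrom = fields[0].removeprefix("chr")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED "
                                 f"coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval "
                                 f"[{start}, {end})")
            rows.append((fields[3], chrom, start / 1e6, end / 1e6))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start_Mb", "end_Mb"])


def write_bed(annotation: pd.DataFrame, path: str | Path,
              header: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(header):
            fh.write(line + "\n")
        for _, r in annotation.iterrows():
            fh.write(f"chr{r['chrom']}\t{int(round(r['start_Mb'] * 1e6))}\t"
                     f"{int(round(r['end_Mb'] * 1e6))}\t{r['gene']}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT row needs name, "
                                 f"description and at least one gene "
                                 f"({len(fields)} fields)")
            sets[fields[0]] = fields[2:]
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc] + list(genes)) + "\n")


def read_expression(path: str | Path, tissue: str = "synthetic",
                    ) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[:2].tolist() != ["probe_id", "gene_id"]:
        raise ValueError(f"{path}: expected first columns "
                         f"'probe_id', 'gene_id'")
    df = df.set_index("probe_id")
    return ExpressionMatrix(values=df.drop(columns="gene_id").astype(float),
                            probe_gene=df["gene_id"], tissue=tissue)


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     header: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    out = expr.values.copy()
    out.insert(0, "gene_id", expr.probe_gene)
    with path.open("w") as fh:
        for line in _header_lines(header):
            fh.write(line + "\n")
        out.to_csv(fh, sep="\t", index_label="probe_id")


def read_strain_matrix(path: str | Path) -> pd.DataFrame:
    """Strain-by-trait matrix CSV (strain rows, trait columns)."""
    return pd.read_csv(path, comment="#", index_col=0)


def write_strain_matrix(matrix: pd.DataFrame, path: str | Path,
                        header: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(header):
            fh.write(line + "\n")
        matrix.to_csv(fh, index_label="strain")
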