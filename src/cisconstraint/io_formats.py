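"""Readers and writers for allele-count tables, GMT gene sets, and result TSVs.

Allele-count tables come in two dialects:

* ``two-file`` — one TSV per allele (the layout produced by splitting a
  combined ASE release into per-allele count files); both files share the
  same gene rows and sample columns.
* ``paired-column`` — a single TSV in which each sample contributes two
  adjacent columns named ``<sample>_a1`` and ``<sample>_a2``.

Gene identifiers are opaque strings matched exactly (case-sensitive).
Missing cells (empty or ``NA``) mean "this sample has no ASE measurement
for this gene" and are stored as NaN — absence, not zero: a zero count is
informative in allele-specific expression while a missing one is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NA_STRINGS = {"", "NA", "NaN", "nan", "na"}


class ParseError(ValueError):
    """Raised when an on-disk table violates the format contract."""


@dataclass
class AlleleCountTable:
    """Biallelic read counts, genes x samples.

    ``counts1``/``counts2`` are float matrices holding non-negative integer
    values, with NaN marking sample-absent cells. For a population cohort
    allele 1 is the reference allele; for an interspecies hybrid it is the
    species-1 (e.g. human) allele.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts1: np.ndarray
    counts2: np.ndarray
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts1 = np.asarray(self.counts1, dtype=float)
        self.counts2 = np.asarray(self.counts2, dtype=float)
        n_genes, n_samples = len(self.gene_ids), len(self.sample_ids)
        if self.counts1.shape != (n_genes, n_samples):
            raise ValueError(
                f"counts1 shape {self.counts1.shape} != ({n_genes}, {n_samples})"
            )
        if self.counts1.shape != self.counts2.shape:
            raise ValueError("counts1 and counts2 must have identical shape")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("sample_ids must be unique")
        for name, m in (("counts1", self.counts1), ("counts2", self.counts2)):
            present = m[~np.isnan(m)]
            if present.size and (present < 0).any():
                raise ValueError(f"{name} contains negative counts")
            if present.size and not np.allclose(present, np.round(present)):
                raise ValueError(f"{name} contains non-integer counts")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)


@dataclass
class GeneSetCollection:
    """Named gene sets with a per-set source label (e.g. the ontology)."""

    sets: dict[str, list[str]]
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def _parse_count(token: str, path: str | Path, lineno: int) -> float:
    token = token.strip()
    if token in _NA_STRINGS:
        return np.nan
    try:
        value = int(token)
    except ValueError as exc:
        raise ParseError(
            f"{path}:{lineno}: count {token!r} is not a non-negative integer"
        ) from exc
    if value < 0:
        raise ParseError(f"{path}:{lineno}: negative count {value}")
    return float(value)


def _read_single_allele_tsv(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}:1: empty header")
        sample_ids = header.split("\t")[1:]
        n_cols = len(sample_ids)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_cols + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols + 1} columns, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            rows.append([_parse_count(tok, path, lineno) for tok in fields[1:]])
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ParseError(f"{path}: duplicate gene ids {dupes[:5]}")
    matrix = np.array(rows, dtype=float) if rows else np.empty((0, n_cols))
    return gene_ids, sample_ids, matrix


def read_allele_counts(
    path: str | Path | tuple[str | Path, str | Path],
    dialect: str = "paired-column",
) -> AlleleCountTable:
    """Read an allele-count table.

    For the ``two-file`` dialect pass a ``(allele1_path, allele2_path)``
    tuple; both files must agree on genes and samples. For ``paired-column``
    pass a single path whose header pairs ``<sample>_a1``/``<sample>_a2``
    columns. Row and column order is preserved from the file.
    """
    if dialect == "two-file":
        if not isinstance(path, tuple) or len(path) != 2:
            raise ValueError("two-file dialect requires a (path1, path2) tuple")
        genes1, samples1, m1 = _read_single_allele_tsv(path[0])
        genes2, samples2, m2 = _read_single_allele_tsv(path[1])
        if genes1 != genes2 or samples1 != samples2:
            raise ParseError("two-file dialect: gene/sample headers disagree")
        return AlleleCountTable(genes1, samples1, m1, m2)
    if dialect == "paired-column":
        genes, columns, matrix = _read_single_allele_tsv(path)
        if len(columns) % 2 != 0:
            raise ParseError(f"{path}: odd number of count columns")
        sample_ids = []
        for i in range(0, len(columns), 2):
            c1, c2 = columns[i], columns[i + 1]
            if not (c1.endswith("_a1") and c2.endswith("_a2") and c1[:-3] == c2[:-3]):
                raise ParseError(
                    f"{path}: columns {c1!r}, {c2!r} are not a <sample>_a1/_a2 pair"
                )
            sample_ids.append(c1[:-3])
        return AlleleCountTable(genes, sample_ids, matrix[:, 0::2], matrix[:, 1::2])
    raise ValueError(f"unknown dialect {dialect!r}")


def _format_count(x: float) -> str:
    return "NA" if np.isnan(x) else str(int(round(x)))


def write_allele_counts(
    table: AlleleCountTable,
    path: str | Path | tuple[str | Path, str | Path],
    dialect: str = "paired-column",
) -> None:
    """Write a table in either dialect (inverse of :func:`read_allele_counts`)."""
    if dialect == "two-file":
        if not isinstance(path, tuple) or len(path) != 2:
            raise ValueError("two-file dialect requires a (path1, path2) tuple")
        for p, matrix in zip(path, (table.counts1, table.counts2)):
            with open(p, "w") as fh:
                fh.write("gene_id\t" + "\t".join(table.sample_ids) + "\n")
                for g, row in zip(table.gene_ids, matrix):
                    fh.write(g + "\t" + "\t".join(_format_count(x) for x in row) + "\n")
        return
    if dialect == "paired-column":
        with open(path, "w") as fh:
            cols = [f"{s}_a{a}" for s in table.sample_ids for a in (1, 2)]
            fh.write("gene_id\t" + "\t".join(cols) + "\n")
            for i, g in enumerate(table.gene_ids):
                cells = []
                for j in range(table.n_samples):
                    cells.append(_format_count(table.counts1[i, j]))
                    cells.append(_format_count(table.counts2[i, j]))
                fh.write(g + "\t" + "\t".join(cells) + "\n")
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, genes...; tab-separated).

    Duplicate genes within a set are deduplicated (first occurrence wins);
    the description field is retained as the set's source label.
    """
    sets: dict[str, list[str]] = {}
    source: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(g for g in genes if g))
            source[name] = desc
    return GeneSetCollection(sets, source)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.source.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def pool_counts_by_individual(
    table: AlleleCountTable, individual_map: Mapping[str, str]
) -> AlleleCountTable:
    """Sum counts over each individual's samples, per gene and allele.

    Used when one donor contributes several libraries (e.g. multiple cell
    types from the same fetal cortex donor) that should count as a single
    statistical unit in the population distribution. A cell is NaN in the
    output only if every pooled sample was absent for that gene.
    """
    unmapped = [s for s in table.sample_ids if s not in individual_map]
    if unmapped:
        raise ValueError(f"samples without an individual mapping: {unmapped[:5]}")
    individuals = list(dict.fromkeys(individual_map[s] for s in table.sample_ids))
    n = table.n_genes
    c1 = np.full((n, len(individuals)), np.nan)
    c2 = np.full((n, len(individuals)), np.nan)
    for k, ind in enumerate(individuals):
        cols = [j for j, s in enumerate(table.sample_ids) if individual_map[s] == ind]
        sub1, sub2 = table.counts1[:, cols], table.counts2[:, cols]
        any_present = ~np.all(np.isnan(sub1) & np.isnan(sub2), axis=1)
        c1[any_present, k] = np.nansum(sub1[any_present], axis=1)
        c2[any_present, k] = np.nansum(sub2[any_present], axis=1)
    return AlleleCountTable(list(table.gene_ids), individuals, c1, c2)


def read_de_summary(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a differential-expression summary TSV: gene, mean_log2fc, de_fdr."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "mean_log2fc", "de_fdr"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: DE summary needs columns {sorted(required)}")
    return {
        str(r.gene_id): (float(r.mean_log2fc), float(r.de_fdr))
        for r in df.itertuples()
    }


def write_de_summary(summary: Mapping[str, tuple[float, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmean_log2fc\tde_fdr\n")
        for gene, (l2fc, fdr) in summary.items():
            fh.write(f"{gene}\t{l2fc:.10g}\t{fdr:.10g}\n")


def read_exclusion_list(path: str | Path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
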