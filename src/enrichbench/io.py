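"""Readers and writers for gene set libraries (GMT) and tabular inputs.

GMT is the tab-separated gene set library format distributed by MSigDB and
Reactome: one set per line as ``name<TAB>description<TAB>gene1<TAB>gene2...``.
Count matrices and differential-expression tables are plain TSV with a header.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

_VERSION_SUFFIX = re.compile(r"\.\d+$")


class GmtParseError(ValueError):
    """A GMT file violates the format contract."""


class SchemaError(ValueError):
    """A tabular input is missing required columns."""


class ValidationError(ValueError):
    """A tabular input has values outside their legal range."""


def normalize_gene_id(gene: str) -> str:
    """Trim whitespace and strip a trailing Ensembl-style ``.N`` version suffix.

    Count tables from aggregators carry versionless Ensembl IDs while DE tools
    may emit versioned ones; a silent mismatch would empty every overlap, so
    identifiers are normalised to the versionless form on ingest. Case is
    preserved.
    """
    return _VERSION_SUFFIX.sub("", gene.strip())


@dataclass
class GeneSetLibrary:
    """A named collection of gene sets with source/version metadata.

    Attributes
    ----------
    name : str
        Library label, e.g. ``"Reactome"``.
    source : str
        Provenance (database or generator) of the library.
    version : str
        Release/version string; empty when unknown.
    sets : dict of str -> frozenset of str
        Mapping from set name to the (deduplicated) member gene identifiers.
    descriptions : dict of str -> str
        Per-set description field (second GMT column).
    """

    name: str = ""
    source: str = ""
    version: str = ""
    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def subset_by_size(self, min_size: int, max_size: int | None = None) -> "GeneSetLibrary":
        """Return a library restricted to sets with ``min_size <= |S| <= max_size``."""
        keep = {
            n: s
            for n, s in self.sets.items()
            if len(s) >= min_size and (max_size is None or len(s) <= max_size)
        }
        return GeneSetLibrary(
            name=self.name,
            source=self.source,
            version=self.version,
            sets=keep,
            descriptions={n: self.descriptions.get(n, "") for n in keep},
        )


def read_gmt(path: str | Path, *, name: str = "", source: str = "", version: str = "") -> GeneSetLibrary:
    """Parse a GMT file into a :class:`GeneSetLibrary`.

    Each line must have at least three tab-separated fields (set name,
    description, one or more genes). Duplicate gene identifiers within a line
    are collapsed; duplicate set names are a hard error because set identity
    is the unit of every downstream statistic. Trailing empty fields and
    Windows line endings are tolerated.

    Raises
    ------
    GmtParseError
        On a malformed line (fewer than three fields), a duplicate set name,
        or a file from which no sets could be parsed.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            set_name = fields[0].strip()
            if set_name in sets:
                raise GmtParseError(f"{path}:{lineno}: duplicate set name {set_name!r}")
            genes = frozenset(
                g for g in (normalize_gene_id(f) for f in fields[2:]) if g
            )
            if not genes:
                raise GmtParseError(f"{path}:{lineno}: set {set_name!r} has no genes")
            sets[set_name] = genes
            descriptions[set_name] = fields[1]
    if not sets:
        raise GmtParseError(f"{path}: no gene sets parsed")
    return GeneSetLibrary(
        name=name or path.stem, source=source, version=version,
        sets=sets, descriptions=descriptions,
    )


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    """Write a library in GMT format.

    Genes are written in sorted order so output is deterministic. Tabs inside
    a description would corrupt the format; they are replaced with spaces and
    a warning is logged.

    Raises
    ------
    ValueError
        If the library has no sets.
    """
    if len(library) == 0:
        raise ValueError("refusing to write an empty gene set library")
    path = Path(path)
    with open(path, "w") as fh:
        for set_name in library.sets:
            desc = library.descriptions.get(set_name, "")
            if "\t" in desc:
                logger.warning(
                    "description of set %r contains tabs; replacing with spaces", set_name
                )
                desc = desc.replace("\t", " ")
            genes = "\t".join(sorted(library.sets[set_name]))
            fh.write(f"{set_name}\t{desc}\t{genes}\n")


def read_de_table(
    path: str | Path,
    *,
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a per-gene differential-expression table.

    Parameters
    ----------
    path : path
        TSV with a header containing gene id, log2 fold change, p-value and
        FDR columns.
    columns : mapping, optional
        Maps the canonical names ``gene``, ``log2fc``, ``p``, ``fdr`` to the
        column names actually present in the file. Defaults to the canonical
        names themselves.

    Returns
    -------
    DataFrame indexed by normalised gene id with columns
    ``log2fc``, ``p``, ``fdr``.
    """
    colmap = {"gene": "gene", "log2fc": "log2fc", "p": "p", "fdr": "fdr"}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    df = df.rename(columns={v: k for k, v in colmap.items()})[["gene", "log2fc", "p", "fdr"]]
    df["gene"] = df["gene"].astype(str).map(normalize_gene_id)
    dup = df["gene"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicated gene id(s): {sorted(df.loc[dup, 'gene'].unique())[:5]}"
        )
    for col in ("p", "fdr"):
        bad = ~df[col].between(0.0, 1.0) | df[col].isna()
        if bad.any():
            raise ValidationError(f"{path}: {col} outside [0,1] for {int(bad.sum())} gene(s)")
    return df.set_index("gene")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene-level count matrix (first column gene id, rest samples).

    Returns a genes x samples DataFrame of non-negative counts with sample
    names preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no genes")
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: no sample columns")
    try:
        mat = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise GmtParseError(f"{path}: non-numeric count cell: {exc}") from exc
    if mat.isna().any().any():
        raise ValidationError(f"{path}: missing count values")
    if (mat < 0).any().any():
        raise ValidationError(f"{path}: negative counts")
    mat.index = [normalize_gene_id(str(g)) for g in mat.index]
    if pd.Index(mat.index).duplicated().any():
        raise ValidationError(f"{path}: duplicated gene ids after normalisation")
    mat.index.name = "gene"
    return mat


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    """Write a DE table (inverse of :func:`read_de_table`)."""
    de.reset_index().to_csv(path, sep="\t", index=False)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a count matrix (inverse of :func:`read_counts`)."""
    counts.to_csv(path, sep="\t")
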