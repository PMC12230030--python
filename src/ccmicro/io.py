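"""Readers and writers for abundance tables, sample metadata and phylogenies.

Tables are tab-separated with taxa as rows and samples as columns (the common
amplicon convention); the orientation is fixed, no transpose heuristic is
attempted. Trees are Newick with branch lengths, parsed through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "ParseError",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "duration_class_of",
    "read_tree",
    "parse_tree",
    "write_tree",
    "patristic_matrix",
]

SHORT_TERM = "short_term"
LONG_TERM = "long_term"
FIRST_YEAR = "first_year"


class ParseError(ValueError):
    """Raised when an input file violates the expected format."""


def duration_class_of(ccy: int) -> str:
    """Map continuous-cropping years to a duration class.

    First year is its own class; 2-10 years is short-term, 15 years and
    beyond long-term. Intermediate values (11-14) do not occur in the
    seven-level gradient design and are rejected.
    """
    ccy = int(ccy)
    if ccy == 1:
        return FIRST_YEAR
    if 2 <= ccy <= 10:
        return SHORT_TERM
    if ccy >= 15:
        return LONG_TERM
    raise ValueError(f"ccy={ccy} has no duration class (gap between 10 and 15)")


@dataclass
class AbundanceTable:
    """Taxon-by-sample abundance matrix.

    ``values`` holds counts (``is_relative=False``) or per-sample relative
    abundances that each sum to one (``is_relative=True``). Rows are taxa,
    columns samples.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    rank: str = "genus"
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D taxon x sample matrix")
        nt, ns = self.values.shape
        if nt != len(self.taxon_ids) or ns != len(self.sample_ids):
            raise ValueError("values shape does not match id lists")
        if len(set(self.taxon_ids)) != nt:
            raise ParseError("duplicate taxon ids")
        if len(set(self.sample_ids)) != ns:
            raise ParseError("duplicate sample ids")
        if nt == 0:
            raise ParseError("no taxa")
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ParseError(
                f"negative abundance at taxon {self.taxon_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.is_relative:
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative-abundance columns must sum to 1")

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_totals(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.taxon_ids, name="taxon"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rank: str = "genus",
                   is_relative: bool = False) -> "AbundanceTable":
        return cls(
            taxon_ids=[str(t) for t in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            rank=rank,
            is_relative=is_relative,
        )

    def relative(self) -> "AbundanceTable":
        """Convert counts to per-sample relative abundances."""
        if self.is_relative:
            return self
        totals = self.sample_totals()
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            raise ValueError(
                f"sample {self.sample_ids[zero[0]]!r} has zero total abundance"
            )
        return replace(self, values=self.values / totals, is_relative=True)

    def subset_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceTable(
            taxon_ids=list(self.taxon_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            rank=self.rank,
            is_relative=self.is_relative,
        )

    def subset_taxa(self, taxon_ids: list[str]) -> "AbundanceTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return AbundanceTable(
            taxon_ids=list(taxon_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
            rank=self.rank,
            is_relative=False if not self.is_relative else self.is_relative,
        )


def read_abundance_table(path, rank: str = "genus",
                         is_relative: bool = False) -> AbundanceTable:
    """Read a TSV abundance table (taxa as rows, first column taxon id)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError("no taxa")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate taxon id {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ParseError(f"non-numeric cell at taxon {row!r}, sample {col!r}")
        # numpy's parser is correctly rounded (full round-trip precision);
        # pandas' to_numeric above is used for error localization only
        values[:, j] = df[col].to_numpy(dtype=float, na_value=np.nan)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"missing cell at taxon {df.index[i]!r}, sample {df.columns[j]!r}")
    return AbundanceTable(
        taxon_ids=[str(t) for t in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
        rank=rank,
        is_relative=is_relative,
    )


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write a table as TSV, preserving values to full float precision."""
    df = table.to_frame()
    if not table.is_relative and np.all(df.to_numpy() == np.floor(df.to_numpy())):
        df = df.astype(int)
        df.to_csv(path, sep="\t")
    else:
        df.to_csv(path, sep="\t", float_format="%.17g")


_META_COLUMNS = ["ccy", "group", "duration_class", "replicate"]


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata: sample_id, ccy, group, duration_class, replicate."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"metadata missing columns {missing}")
    if df.index.duplicated().any():
        raise ParseError("duplicate sample ids in metadata")
    df["ccy"] = df["ccy"].astype(int)
    for sid, row in df.iterrows():
        expected = duration_class_of(row["ccy"])
        if row["duration_class"] != expected:
            raise ParseError(
                f"sample {sid!r}: duration_class {row['duration_class']!r} "
                f"inconsistent with ccy={row['ccy']} (expected {expected!r})")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def parse_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted Newick string with branch lengths and unique tips."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ParseError(f"unparseable Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()
              if leaf.taxon is not None]
    if len(labels) < 2:
        raise ParseError("tree must have at least 2 tips")
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"duplicate tip label(s): {dup}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ParseError("tree has edges without branch lengths")
    return tree


def read_tree(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_tree(fh.read())


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def patristic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip labels and the matrix of pairwise patristic (branch-length) distances."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            dist[i, j] = dist[j, i] = d
    return labels, dist
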