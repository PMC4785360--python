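"""Readers and writers for the external formats the pipeline touches.

Formats
-------
* expression matrix — tab-delimited, genes in rows, samples in columns
  (orientation auto-detected or forced with ``orientation_hint``)
* sample annotation table — tab-delimited with the covariate columns
  ``sample, age, sex, batch, cancer, tissue, pc1..pc3`` plus one
  ``sens_<drug>`` activity-area column per drug
* gene-set collections — GMT (set name, description, member genes per line)
* protein-interaction networks — 3-column edge list ``geneA geneB score``,
  STRING-style 0–1000 scores auto-rescaled to [0, 1]

All writers accept a ``params`` mapping that is recorded as ``# key=value``
header comments; all readers skip ``#`` lines, so files round-trip.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: covariate columns every sample table must provide
SAMPLE_COLUMNS = ("sample", "age", "sex", "batch", "cancer", "tissue", "pc1", "pc2", "pc3")

#: prefix naming per-drug activity-area columns, e.g. ``sens_17-AAG``
SENSITIVITY_PREFIX = "sens_"

#: categorical covariates that enter regressions as factors
FACTOR_COLUMNS = ("sex", "batch", "cancer", "tissue")

#: numeric covariates that enter regressions as-is
NUMERIC_COLUMNS = ("age", "pc1", "pc2", "pc3")


def _comment_lines(params: Mapping[str, object] | None) -> str:
    if not params:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in params.items())


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def validate_expression_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the genes × samples invariants and return the frame unchanged."""
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene identifiers: {dups[:5]}")
    if expr.columns.duplicated().any():
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample identifiers: {dups[:5]}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = expr.columns[[not np.issubdtype(d, np.number) for d in expr.dtypes]]
        raise ParseError(f"non-numeric expression columns: {list(bad)[:5]}")
    if not np.isfinite(values).all():
        gi, si = np.argwhere(~np.isfinite(values))[0]
        raise ParseError(
            f"non-finite expression value for gene {expr.index[gi]!r} "
            f"in sample {expr.columns[si]!r}"
        )
    return expr


def read_expression_matrix(
    path,
    orientation_hint: str | None = None,
    known_sample_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Read a tab-delimited expression matrix, normalised to genes-in-rows.

    Orientation is resolved by ``orientation_hint`` (``"genes_in_rows"`` or
    ``"samples_in_rows"``); otherwise, if ``known_sample_ids`` is given the
    axis overlapping it most is taken as the sample axis; otherwise
    genes-in-rows is assumed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise ParseError(
                f"non-numeric expression value {bad.iloc[0]!r} for gene "
                f"{gene!r} in column {col!r} of {path}"
            )
    if df.isna().to_numpy().any():
        gi, si = np.argwhere(df.isna().to_numpy())[0]
        raise ParseError(
            f"missing expression value for gene {df.index[gi]!r} "
            f"in sample {df.columns[si]!r} of {path}"
        )

    if orientation_hint is not None:
        if orientation_hint not in ("genes_in_rows", "samples_in_rows"):
            raise ValueError(f"unknown orientation_hint {orientation_hint!r}")
        if orientation_hint == "samples_in_rows":
            df = df.T
    elif known_sample_ids is not None:
        known = set(map(str, known_sample_ids))
        col_hits = len(known.intersection(df.columns))
        row_hits = len(known.intersection(df.index))
        if row_hits > col_hits:
            df = df.T
    df.index.name = None
    df.columns.name = None
    return validate_expression_matrix(df)


def write_expression_matrix(expr: pd.DataFrame, path, params: Mapping | None = None) -> None:
    validate_expression_matrix(expr)
    with open(path, "w") as fh:
        fh.write(_comment_lines(params))
        expr.to_csv(fh, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------

def drug_names(samples: pd.DataFrame) -> list[str]:
    """Drugs with a ``sens_<drug>`` column in the table."""
    return [c[len(SENSITIVITY_PREFIX):] for c in samples.columns
            if c.startswith(SENSITIVITY_PREFIX)]


def sensitivity_column(drug: str) -> str:
    return SENSITIVITY_PREFIX + drug


def read_sample_table(path) -> pd.DataFrame:
    """Read per-sample covariates and drug sensitivities, indexed by sample id.

    Rows with a missing sensitivity for some drug are kept (NaN), never
    dropped: per-drug analysis subsets are formed downstream, so sample
    counts may legitimately differ between drugs.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str},
                     float_precision="round_trip")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample table {path} is missing columns: {missing}")
    if df["sample"].duplicated().any():
        dups = df["sample"][df["sample"].duplicated()].tolist()
        raise FormatError(f"duplicate sample identifiers: {dups[:5]}")
    if (df["age"].dropna() < 0).any():
        bad = df.loc[df["age"] < 0, "sample"].iloc[0]
        raise ValidationError(f"negative age for sample {bad!r}")
    for col in FACTOR_COLUMNS:
        if df[col].isna().any() or (df[col].astype(str).str.len() == 0).any():
            # tolerated at parse time; these samples drop out per-drug later
            n_bad = int(df[col].isna().sum())
            logger.warning("sample table: %d empty values in %r", n_bad, col)
        df[col] = df[col].astype(str)
    sens_cols = [c for c in df.columns if c.startswith(SENSITIVITY_PREFIX)]
    for col in sens_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().sum() > df[col].isna().sum():
            raise ParseError(f"non-numeric sensitivity in column {col!r}")
        df[col] = vals
    return df.set_index("sample", drop=False)


def write_sample_table(samples: pd.DataFrame, path, params: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_lines(params))
        samples.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions.

    ``sets`` maps set name → member genes (deduplicated, order preserved in
    files but held as a frozenset here); ``descriptions`` maps name → text.
    """

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene-set name {name!r}")
        self.sets[name] = frozenset(map(str, members))
        self.descriptions[name] = description

    def restricted(self, universe: Iterable[str], min_size: int = 0) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets below ``min_size``."""
        uni = frozenset(map(str, universe))
        out = GeneSetCollection()
        for name, members in self.sets.items():
            kept = members & uni
            if len(kept) >= min_size:
                out.add(name, kept, self.descriptions.get(name, ""))
        return out


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file; duplicate members in a line are collapsed."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in coll:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            coll.add(name, genes, desc)
    return coll


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def read_network_edges(path, min_confidence: float = 0.4) -> nx.Graph:
    """Read a weighted edge list into an undirected simple graph.

    Scores are auto-scaled: if the maximum score exceeds 1 the STRING
    convention (0–1000) is assumed and scores are divided by 1000 before
    thresholding.  Self-loops are dropped with a warning; duplicate edges
    keep the maximum score; only edges with score >= ``min_confidence``
    are retained, and isolated nodes are absent.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["a", "b", "score"], dtype={"a": str, "b": str})
    scores = pd.to_numeric(df["score"], errors="coerce")
    # tolerate a single header line (e.g. STRING's "protein1 protein2
    # combined_score") but only when the remaining rows parse
    if len(df) > 1 and np.isnan(scores.iloc[0]) and scores.iloc[1:].notna().all():
        df, scores = df.iloc[1:], scores.iloc[1:]
    if scores.isna().any():
        row = df.loc[scores.isna()].iloc[0]
        raise ParseError(f"unparsable score {row['score']!r} for edge {row['a']}-{row['b']}")
    df = df.assign(score=scores)
    loops = df["a"] == df["b"]
    if loops.any():
        logger.warning("dropping %d self-loop edges", int(loops.sum()))
        df = df[~loops]
    if len(df) and df["score"].max() > 1:
        df = df.assign(score=df["score"] / 1000.0)
    graph = nx.Graph()
    for a, b, score in df.itertuples(index=False):
        if score < min_confidence:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["weight"] = max(graph[a][b]["weight"], float(score))
        else:
            graph.add_edge(a, b, weight=float(score))
    return graph


def write_network_edges(graph: nx.Graph, path, params: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_lines(params))
        for a, b, data in graph.edges(data=True):
            w = data.get("weight", 1.0)
            fh.write(f"{a}\t{b}\t{w:g}\n")


# ---------------------------------------------------------------------------
# generic results tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, params: Mapping | None = None,
                index: bool = False) -> None:
    """Write a results table as TSV with a ``# key=value`` parameter header."""
    with open(path, "w") as fh:
        fh.write(_comment_lines(params))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
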