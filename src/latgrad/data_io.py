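"""Input/output and species matching.

Reads Newick trees and delimited trait tables, reconciles the species sets,
and assigns equal-count absolute-latitude quartiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .phylo import Phylogeny, normalize_label

__all__ = [
    "TRAIT_COLUMNS",
    "REQUIRED_COLUMNS",
    "QUARTILE_LABELS",
    "load_tree",
    "load_traits",
    "write_traits",
    "match_tree_traits",
    "assign_latitude_quartiles",
]

logger = logging.getLogger(__name__)

#: the eight linear measurements, in canonical column order
TRAIT_COLUMNS = [
    "std_length",
    "jaw_length",
    "mouth_width",
    "body_width",
    "body_depth",
    "ped_width",
    "ped_depth",
    "head_depth",
]

REQUIRED_COLUMNS = ["species"] + TRAIT_COLUMNS + ["lat_centroid"]

#: quartile labels ordered by increasing absolute latitude
QUARTILE_LABELS = ["lower", "second", "third", "upper"]


def load_tree(path) -> Phylogeny:
    """Read a Newick file; labels are whitespace-normalized.

    Raises on duplicate tip labels or nonpositive branch lengths; merely
    warns when the tree is not ultrametric within tolerance.
    """
    with open(path) as fh:
        text = fh.read()
    tree = Phylogeny.from_newick(text)
    tree.validate()
    return tree


def load_traits(path, sep=None) -> pd.DataFrame:
    """Read a species x trait table (CSV/TSV, inferred delimiter).

    Rows with any missing required value are dropped (count logged).
    Latitude centroids must lie in [-90, 90].
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = df.copy()
    df["species"] = df["species"].astype(str).map(normalize_label)
    n0 = len(df)
    df = df.dropna(subset=REQUIRED_COLUMNS)
    dropped = n0 - len(df)
    if dropped:
        logger.info("%d row%s dropped (missing values)", dropped, "s" if dropped > 1 else "")
    lat = df["lat_centroid"].astype(float)
    bad = (lat < -90) | (lat > 90)
    if bad.any():
        raise ValueError(
            f"latitude centroid out of range [-90, 90] for species: "
            f"{df.loc[bad, 'species'].tolist()}"
        )
    if df["species"].duplicated().any():
        dupes = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species rows: {dupes}")
    return df.reset_index(drop=True)


def write_traits(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def match_tree_traits(tree: Phylogeny, table: pd.DataFrame):
    """Prune tree and table to their common species set, aligning orders.

    The returned table row order follows the pruned tree's tip order.
    """
    tree_set = set(tree.tip_labels)
    table_set = set(table["species"])
    common = tree_set & table_set
    if not common:
        raise ValueError("tree and trait table share no species")
    pruned = tree.prune_to(common) if common != tree_set else tree
    sub = table[table["species"].isin(common)]
    sub = sub.set_index("species").loc[pruned.tip_labels].reset_index()
    return pruned, sub


def assign_latitude_quartiles(table: pd.DataFrame) -> pd.DataFrame:
    """Label each species by equal-count quartile of absolute latitude.

    Species are ranked by (|lat_centroid|, species) ascending; the n mod 4
    leftover species go to the lowest-index bins.  Ties at a breakpoint are
    therefore resolved by species-label order.  Adds a ``quartile`` column
    with values lower/second/third/upper.
    """
    n = len(table)
    if n < 4:
        raise ValueError(f"need at least 4 species to form quartiles, got {n}")
    abs_lat = table["lat_centroid"].abs().to_numpy()
    order = sorted(range(n), key=lambda i: (abs_lat[i], table["species"].iloc[i]))
    base, rem = divmod(n, 4)
    sizes = [base + (1 if b < rem else 0) for b in range(4)]
    quart = np.empty(n, dtype=object)
    pos = 0
    for b, size in enumerate(sizes):
        for i in order[pos : pos + size]:
            quart[i] = QUARTILE_LABELS[b]
        pos += size
    out = table.copy()
    out["quartile"] = pd.Categorical(quart, categories=QUARTILE_LABELS)
    return out


def quartile_breakpoints(table: pd.DataFrame) -> list:
    """Max |latitude| within each of the first three quartile bins."""
    if "quartile" not in table.columns:
        table = assign_latitude_quartiles(table)
    abs_lat = table["lat_centroid"].abs()
    return [
        float(abs_lat[table["quartile"] == q].max()) for q in QUARTILE_LABELS[:3]
    ]
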