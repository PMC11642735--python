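"""Reading, writing and reconciling phylogenies with karyotype and trait tables.

Trees are represented as :class:`dendropy.Tree` objects throughout the
package.  Branch lengths are interpreted as time in millions of years (MY).
Species names are matched *exactly* after a light normalisation (whitespace
trimmed, underscores replaced by spaces); no fuzzy matching is attempted,
because silent approximate joins corrupt comparative datasets.
"""

from __future__ import annotations

import io
import logging
import warnings

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NewickError",
    "read_newick",
    "write_newick",
    "normalize_name",
    "read_karyotype_table",
    "read_trait_table",
    "match_tree_data",
    "drop_tips",
    "validate_tree",
]

#: columns recognised in trait tables
TRAIT_COLUMNS = ("species", "mass_g", "range_km2", "trophic", "abundance",
                 "migratory", "order")

TROPHIC_LEVELS = ("herbivore", "omnivore", "carnivore")


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed or is incomplete."""


def normalize_name(name: str) -> str:
    """Normalise a species name: trim whitespace, underscores -> spaces."""
    return str(name).strip().replace("_", " ")


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree with branch lengths.

    Quoted labels and square-bracket comments are tolerated and stripped.
    Every non-root edge must carry a strictly positive branch length.

    Raises
    ------
    NewickError
        If the string is malformed (the dendropy message, which names the
        offending position, is preserved) or any branch length is missing
        or non-positive.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=False,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error classes
        raise NewickError(f"malformed Newick: {exc}") from exc
    validate_tree(tree)
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree to Newick with >= 10 significant digits on branches."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    )
    return s.strip() + ("\n" if not s.endswith("\n") else "")


def validate_tree(tree: dendropy.Tree) -> None:
    """Check structural invariants: one root, positive branch lengths,
    unique tip labels.  Raises ``NewickError`` on violation."""
    root = tree.seed_node
    if root.edge.length is not None and root.edge.length not in (0, 0.0):
        if root.edge.length < 0:
            raise NewickError("root edge length must be absent or zero")
    labels = []
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        bl = node.edge.length
        if bl is None:
            raise NewickError(
                f"missing branch length on edge above "
                f"{node.taxon.label if node.taxon else 'an internal node'}"
            )
        if not np.isfinite(bl) or bl <= 0:
            raise NewickError(f"non-positive branch length {bl!r}")
        if node.is_leaf():
            if node.taxon is None:
                raise NewickError("unlabeled tip")
            labels.append(node.taxon.label)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate tip labels: {dupes}")


def _read_table(source, sep=None) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    if isinstance(source, str) and ("\n" in source or "," in source and "/" not in source):
        # allow raw CSV text for convenience in tests and docs
        try:
            return pd.read_csv(io.StringIO(source), sep=sep, engine="python")
        except Exception:
            pass
    return pd.read_csv(source, sep=sep, engine="python")


def read_karyotype_table(source, *, diploid: bool = False, sep=None) -> pd.DataFrame:
    """Load a karyotype table (columns ``species, n_total[, n_macro, n_micro]``).

    Multiple records per species are collapsed to the modal haploid count;
    a tie is resolved to the lowest count with a warning.  With
    ``diploid=True`` the counts are interpreted as 2n and halved (an odd 2n
    is an error).

    Returns a DataFrame indexed by normalised species name with integer
    columns ``n_total`` and, where present, ``n_macro`` / ``n_micro``.
    """
    df = _read_table(source, sep=sep)
    if "species" not in df.columns or "n_total" not in df.columns:
        raise ValueError("karyotype table needs 'species' and 'n_total' columns")
    df = df.copy()
    df["species"] = df["species"].map(normalize_name)

    count_cols = [c for c in ("n_total", "n_macro", "n_micro") if c in df.columns]
    for c in count_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        if (vals.dropna() <= 0).any() or (vals.dropna() % 1 != 0).any():
            raise ValueError(f"column {c!r} must hold positive integers")
        df[c] = vals
    if diploid:
        for c in count_cols:
            odd = df[c].dropna() % 2 != 0
            if odd.any():
                bad = df.loc[odd[odd].index, "species"].tolist()
                raise ValueError(f"odd diploid count for {bad}; cannot halve")
            df[c] = df[c] / 2

    def _modal(series: pd.Series):
        s = series.dropna().astype(int)
        if s.empty:
            return np.nan
        counts = s.value_counts()
        top = counts[counts == counts.max()].index
        if len(top) > 1:
            warnings.warn(
                f"tied modal counts {sorted(top)}; taking the lowest",
                stacklevel=2,
            )
        return int(min(top))

    out = df.groupby("species", sort=True)[count_cols].agg(_modal)
    out = out.dropna(subset=["n_total"])
    for c in count_cols:
        out[c] = out[c].astype("Int64")
    both = out.notna().all(axis=1)
    if {"n_macro", "n_micro"}.issubset(out.columns):
        bad = both & (out["n_macro"] + out["n_micro"] != out["n_total"])
        if bad.any():
            raise ValueError(
                f"macro + micro != total for {out.index[bad].tolist()}"
            )
    return out


def read_trait_table(source, sep=None) -> pd.DataFrame:
    """Load a per-species trait table; see :data:`TRAIT_COLUMNS`.

    Species names are normalised and must be unique; numeric traits must be
    non-negative; the ``trophic`` column, when present, is restricted to
    herbivore/omnivore/carnivore.
    """
    df = _read_table(source, sep=sep)
    if "species" not in df.columns:
        raise ValueError("trait table needs a 'species' column")
    df = df.copy()
    df["species"] = df["species"].map(normalize_name)
    if df["species"].duplicated().any():
        dupes = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in trait table: {dupes}")
    for c in ("mass_g", "range_km2", "abundance"):
        if c in df.columns:
            vals = pd.to_numeric(df[c], errors="coerce")
            if (vals.dropna() < 0).any():
                raise ValueError(f"negative values in {c!r}")
            df[c] = vals
    if "trophic" in df.columns:
        labels = set(df["trophic"].dropna())
        unknown = labels - set(TROPHIC_LEVELS)
        if unknown:
            raise ValueError(f"unknown trophic labels: {sorted(unknown)}")
    return df.set_index("species", drop=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the tree's stable (postorder leaf) traversal order."""
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def match_tree_data(tree: dendropy.Tree, table: pd.DataFrame):
    """Prune a tree and a species-indexed table to their shared species.

    Returns ``(pruned_tree, aligned)`` where ``aligned`` is the table
    re-indexed to the pruned tree's tip order.  Dropped names (from either
    side) are reported through the module logger.  Fewer than two shared
    species is an error.

    The input tree is not modified.  The operation is idempotent.
    """
    tree_names = set(tip_labels(tree))
    table_names = set(map(normalize_name, table.index))
    shared = tree_names & table_names
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} species shared between tree and table"
        )
    dropped_tree = sorted(tree_names - shared)
    dropped_table = sorted(table_names - shared)
    if dropped_tree:
        logger.info("dropping %d tree tips without data: %s",
                    len(dropped_tree), dropped_tree)
    if dropped_table:
        logger.info("dropping %d table rows not in tree: %s",
                    len(dropped_table), dropped_table)
    pruned = tree
    if dropped_tree:
        pruned = drop_tips(tree, dropped_tree)
    t2 = table.copy()
    t2.index = [normalize_name(s) for s in t2.index]
    aligned = t2.loc[tip_labels(pruned)]
    return pruned, aligned


def drop_tips(tree: dendropy.Tree, names) -> dendropy.Tree:
    """Return a copy of the tree with the named tips removed.

    Unifurcations created by the removal are suppressed with branch lengths
    summed, so root-to-tip path lengths of surviving tips are unchanged.
    """
    names = [normalize_name(n) for n in names]
    have = set(tip_labels(tree))
    unknown = sorted(set(names) - have)
    if unknown:
        raise ValueError(f"tips not in tree: {unknown}")
    if not names:
        return tree.clone(depth=1)
    survivors = have - set(names)
    if len(survivors) < 2:
        raise ValueError("fewer than 2 tips would remain")
    pruned = tree.clone(depth=1)
    keep = [t for t in pruned.taxon_namespace if t.label in survivors]
    pruned.retain_taxa(keep)
    # dendropy can leave a root with a single child; splice it out
    root = pruned.seed_node
    while len(root.child_nodes()) == 1:
        only = root.child_nodes()[0]
        for gc in list(only.child_nodes()):
            only.remove_child(gc)
            root.add_child(gc)
            if gc.edge.length is not None and only.edge.length:
                gc.edge.length += only.edge.length
        root.remove_child(only)
    validate_tree(pruned)
    return pruned
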