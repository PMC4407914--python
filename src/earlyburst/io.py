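"""Readers and writers for trees (Newick/NEXUS) and tabular inputs.

All tabular interchange is TSV with a header row, UTF-8.  Tree files
serialize branch lengths in myr; node ages in any tabular output are
reported before present (tips at 0).
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .tree import TimeTree, TreeError

__all__ = [
    "read_trees",
    "write_trees",
    "read_traits",
    "write_traits",
    "read_richness",
    "write_richness",
    "read_intervals",
]


def read_trees(path, schema: str = "auto") -> List[TimeTree]:
    """Read one or more trees from a Newick or NEXUS file.

    ``schema`` is ``newick``, ``nexus`` or ``auto`` (sniffed from the
    leading ``#NEXUS`` token).  Order is preserved.  Non-ultrametric
    trees are accepted here; stages requiring ultrametricity reject
    them at use.
    """
    import dendropy

    path = Path(path)
    text = path.read_text()
    if schema == "auto":
        schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        tl = dendropy.TreeList.get(
            data=text, schema=schema, preserve_underscores=True
        )
    except Exception as exc:
        raise TreeError(f"cannot parse {path} as {schema}: {exc}") from exc
    if not tl:
        raise TreeError(f"no trees found in {path}")
    return [TimeTree.from_dendropy(t) for t in tl]


def write_trees(trees: Sequence[TimeTree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.newick() + "\n")


def read_traits(path) -> pd.DataFrame:
    """Species-by-trait table from TSV.

    Accepts either wide format (``species`` column plus one column per
    trait) or long format (``species``, ``trait``, ``value``).  Missing
    cells stay missing (NaN), never zero-filled; non-numeric trait
    cells raise with the offending row named.
    """
    df = pd.read_csv(path, sep="\t")
    if "species" not in df.columns:
        raise ValueError(f"{path}: expected a 'species' column")
    if {"trait", "value"} <= set(df.columns):
        wide = df.pivot(index="species", columns="trait", values="value")
        wide.columns.name = None
    else:
        wide = df.set_index("species")
    for col in wide.columns:
        try:
            wide[col] = pd.to_numeric(wide[col])
        except (ValueError, TypeError) as exc:
            bad = wide.index[
                pd.to_numeric(wide[col], errors="coerce").isna() & wide[col].notna()
            ].tolist()
            raise ValueError(
                f"{path}: non-numeric values for trait {col!r} in rows {bad}"
            ) from exc
    return wide


def write_traits(frame: pd.DataFrame, path, long: bool = False) -> None:
    if long:
        out = frame.reset_index().melt(
            id_vars=frame.index.name or "index", var_name="trait", value_name="value"
        )
        out.columns = ["species", "trait", "value"]
        out.to_csv(path, sep="\t", index=False)
    else:
        frame.rename_axis("species").to_csv(path, sep="\t")


def read_richness(path) -> pd.Series:
    """Tip-to-richness table: TSV with columns ``tip`` (or ``species``)
    and ``n_species``; counts must be positive integers."""
    df = pd.read_csv(path, sep="\t")
    key = "tip" if "tip" in df.columns else "species"
    if key not in df.columns or "n_species" not in df.columns:
        raise ValueError(f"{path}: expected columns 'tip'/'species' and 'n_species'")
    vals = df["n_species"]
    as_num = pd.to_numeric(vals, errors="coerce")
    bad = df[key][as_num.isna() | (as_num != np.floor(as_num)) | (as_num < 1)].tolist()
    if bad:
        raise ValueError(f"{path}: richness must be integer >= 1; bad rows: {bad}")
    return pd.Series(as_num.astype(np.int64).values, index=df[key].values, name="n_species")


def write_richness(richness: pd.Series, path) -> None:
    richness.rename_axis("tip").rename("n_species").to_csv(path, sep="\t")


def read_intervals(path) -> list:
    """Geological intervals from TSV columns name, old_Ma, young_Ma."""
    from .kmrates import GeoInterval

    df = pd.read_csv(path, sep="\t")
    return [
        GeoInterval(str(r["name"]), float(r["old_Ma"]), float(r["young_Ma"]))
        for _, r in df.iterrows()
    ]
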