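"""Readers/writers for outline coordinates, trait tables, and trees.

Coordinate files come in two dialects:

* ``block-text`` — repeated blocks of an identifier line followed by one
  whitespace-delimited ``x y`` pair per line; blank lines optional
  between blocks.
* ``tps`` — standard TPS landmark files (``LM=n`` count line, ``n``
  coordinate lines, ``ID=name``).

The trait table is delimited text with a header carrying at least a
species column and a feeding-class column; classes are normalised to
lower case and any string other than browser/grazer maps to unknown
(with a warning).  Trees are Newick.  ``reconcile`` restricts all three
inputs to their common species, pruning the tree with subtending branch
lengths summed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .outline import SemilandmarkSet
from . import trees as _trees

logger = logging.getLogger(__name__)

KNOWN_CLASSES = ("browser", "grazer")


@dataclass
class CoordinateDataset:
    """Ordered collection of per-specimen outline configurations."""

    specimens: list[SemilandmarkSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.species_id for s in self.specimens]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self):
        return iter(self.specimens)

    @property
    def ids(self) -> list[str]:
        return [s.species_id for s in self.specimens]

    def get(self, species_id: str) -> SemilandmarkSet:
        for s in self.specimens:
            if s.species_id == species_id:
                return s
        raise KeyError(species_id)

    def subset(self, ids) -> "CoordinateDataset":
        wanted = set(ids)
        return CoordinateDataset([s for s in self.specimens if s.species_id in wanted])


class ParseError(ValueError):
    pass


def _parse_block_text(lines: list[str], path: str) -> CoordinateDataset:
    specimens: list[SemilandmarkSet] = []
    current_id, pts, start_line = None, [], 0

    def flush(lineno):
        nonlocal current_id, pts
        if current_id is None:
            return
        if len(pts) < 3:
            raise ParseError(
                f"{path}:{start_line}: specimen {current_id!r} has "
                f"{len(pts)} coordinate pairs (need >= 3)"
            )
        specimens.append(SemilandmarkSet(current_id, np.array(pts)))
        current_id, pts = None, []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        is_pair = len(fields) == 2
        if is_pair:
            try:
                xy = (float(fields[0]), float(fields[1]))
            except ValueError:
                is_pair = False
        if is_pair:
            if current_id is None:
                raise ParseError(f"{path}:{lineno}: coordinate pair before any id line")
            pts.append(xy)
        else:
            if len(fields) > 2:
                raise ParseError(f"{path}:{lineno}: malformed line {raw.strip()!r}")
            flush(lineno)
            current_id, start_line = line, lineno
    flush(len(lines))
    if not specimens:
        raise ParseError(f"{path}: no specimens found (empty or malformed file)")
    return CoordinateDataset(specimens)


def _parse_tps(lines: list[str], path: str) -> CoordinateDataset:
    specimens: list[SemilandmarkSet] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.upper().startswith("LM="):
            raise ParseError(f"{path}:{i}: expected LM= line, got {line!r}")
        try:
            count = int(line.split("=", 1)[1])
        except ValueError:
            raise ParseError(f"{path}:{i}: bad landmark count {line!r}") from None
        pts = []
        for _ in range(count):
            if i >= len(lines):
                raise ParseError(f"{path}:{i}: truncated coordinate block")
            fields = lines[i].split()
            i += 1
            if len(fields) != 2:
                raise ParseError(f"{path}:{i}: expected 'x y', got {lines[i-1]!r}")
            try:
                pts.append((float(fields[0]), float(fields[1])))
            except ValueError:
                raise ParseError(
                    f"{path}:{i}: non-numeric coordinate {lines[i-1].strip()!r}"
                ) from None
        spec_id = None
        while i < len(lines) and lines[i].strip() and not lines[i].strip().upper().startswith("LM="):
            tag = lines[i].strip()
            i += 1
            if tag.upper().startswith("ID="):
                spec_id = tag.split("=", 1)[1].strip()
        if spec_id is None:
            raise ParseError(f"{path}:{i}: TPS block missing ID= line")
        specimens.append(SemilandmarkSet(spec_id, np.array(pts)))
    if not specimens:
        raise ParseError(f"{path}: no specimens found")
    return CoordinateDataset(specimens)


def read_coordinates(path, dialect: str = "block-text") -> CoordinateDataset:
    """Read outline coordinates; point order is preserved exactly as read."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if dialect == "block-text":
        return _parse_block_text(lines, str(path))
    if dialect == "tps":
        return _parse_tps(lines, str(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_coordinates(dataset: CoordinateDataset, path, dialect: str = "block-text") -> None:
    """Write coordinates with shortest round-trip float formatting."""
    out = []
    for s in dataset:
        if dialect == "block-text":
            out.append(s.species_id)
            out.extend(f"{float(x)!r} {float(y)!r}" for x, y in s.points)
            out.append("")
        elif dialect == "tps":
            out.append(f"LM={s.p}")
            out.extend(f"{float(x)!r} {float(y)!r}" for x, y in s.points)
            out.append(f"ID={s.species_id}")
            out.append("")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    Path(path).write_text("\n".join(out))


def read_traits(
    path,
    species_column: str = "species",
    class_column: str = "feeding_class",
    mass_column: str = "body_mass_g",
    sep: str = ",",
) -> pd.DataFrame:
    """Read the specimen trait table.

    Returns a DataFrame indexed by species id with a ``feeding_class``
    column normalised to {browser, grazer, unknown} and, when present, a
    positive ``body_mass_g`` column.
    """
    df = pd.read_csv(path, sep=sep)
    for col in (species_column, class_column):
        if col not in df.columns:
            raise ValueError(f"trait table missing column {col!r}")
    if df[species_column].duplicated().any():
        raise ValueError("duplicate species ids in trait table")
    df = df.set_index(species_column)
    cls = df[class_column].astype(str).str.strip().str.lower()
    unrecognised = sorted(set(cls) - set(KNOWN_CLASSES) - {"unknown"})
    if unrecognised:
        logger.warning(
            "unrecognised feeding classes mapped to 'unknown': %s", unrecognised
        )
    df["feeding_class"] = cls.where(cls.isin(KNOWN_CLASSES), "unknown")
    if mass_column in df.columns and mass_column != "body_mass_g":
        df = df.rename(columns={mass_column: "body_mass_g"})
    if "body_mass_g" in df.columns:
        mass = pd.to_numeric(df["body_mass_g"], errors="coerce")
        bad = df.index[mass.notna() & (mass <= 0)].tolist()
        if bad:
            raise ValueError(f"non-positive body mass for: {bad}")
        df["body_mass_g"] = mass
    return df


def read_tree(path) -> dendropy.Tree:
    """Read a rooted Newick tree with unique tip labels."""
    return _trees.parse_newick(Path(path).read_text())


def write_tree(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", unquoted_underscores=True)
    )


def normalise_name(name: str) -> str:
    """Matching key: trimmed, case-folded, spaces unified to underscores."""
    return "_".join(str(name).strip().casefold().split()).replace(" ", "_")


def reconcile(
    dataset: CoordinateDataset,
    traits: pd.DataFrame,
    tree: dendropy.Tree | None = None,
):
    """Restrict all inputs to their common species.

    Species names are matched after trimming, case-folding, and
    space/underscore unification; outputs use the coordinate dataset's
    original identifiers (trait rows reindexed, tree tips relabelled).
    The tree is pruned with subtending branch lengths summed.  Returns
    ``(dataset, traits, tree, report)`` where ``report`` lists the names
    dropped from each input.
    """
    coord_keys = {normalise_name(i): i for i in dataset.ids}
    trait_keys = {normalise_name(i): i for i in traits.index}
    shared = set(coord_keys) & set(trait_keys)
    tree_keys = None
    if tree is not None:
        tree_keys = {normalise_name(t): t for t in _trees.tip_labels(tree)}
        shared &= set(tree_keys)
    if not shared:
        raise ValueError("no species shared by all inputs after name matching")
    keep_ids = [i for i in dataset.ids if normalise_name(i) in shared]
    report = {
        "n_retained": len(keep_ids),
        "dropped_coordinates": [i for i in dataset.ids if normalise_name(i) not in shared],
        "dropped_traits": [i for i in traits.index if normalise_name(i) not in shared],
        "dropped_tree_tips": [],
    }
    new_dataset = dataset.subset(keep_ids)
    new_traits = traits.loc[[trait_keys[normalise_name(i)] for i in keep_ids]].copy()
    new_traits.index = keep_ids
    new_tree = None
    if tree is not None:
        report["dropped_tree_tips"] = [
            t for t in _trees.tip_labels(tree) if normalise_name(t) not in shared
        ]
        new_tree = _trees.prune_to(tree, [tree_keys[normalise_name(i)] for i in keep_ids])
        relabel = {tree_keys[normalise_name(i)]: i for i in keep_ids}
        for taxon in new_tree.taxon_namespace:
            taxon.label = relabel.get(taxon.label, taxon.label)
    if report["dropped_coordinates"] or report["dropped_traits"] or report["dropped_tree_tips"]:
        logger.info(
            "reconcile: retained %d species; dropped %d coordinate, %d trait, %d tree entries",
            len(keep_ids), len(report["dropped_coordinates"]),
            len(report["dropped_traits"]), len(report["dropped_tree_tips"]),
        )
    return new_dataset, new_traits, new_tree, report
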