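"""Shared data model for the barcode delimitation pipeline.

Containers are deliberately thin: an :class:`Alignment` is a list of equally
long nucleotide strings, a :class:`Partition` is a specimen -> group mapping,
a :class:`CommunityMatrix` is a 0/1 species-by-site incidence table, and an
:class:`UltrametricTree` wraps a dendropy tree whose node ages have been
validated.  All downstream analyses (distances, clustering, GMYC, congruence,
beta-diversity) consume only these types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input: duplicate ids, empty files, unlabeled tips, ..."""


class AlignmentError(ValueError):
    """Sequences that cannot form an alignment (unequal lengths)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a model assumption."""


#: Characters contributing to a pairwise comparison.  Everything else
#: (gaps, N, ?, IUPAC ambiguity codes) is treated as missing under pairwise
#: deletion, while being stored verbatim in the alignment.
UNAMBIGUOUS_BASES = frozenset("ACGT")

#: Full set of characters an alignment may contain.
ALLOWED_CHARS = frozenset("ACGTRYSWKMBDHVN-?")

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i

#: Sentinel code for a missing/ambiguous character in encoded alignments.
MISSING_CODE = 255


@dataclass(frozen=True)
class Alignment:
    """An aligned set of barcode sequences (equal length, unique ids)."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise FormatError("alignment contains no sequences")
        if len(self.ids) != len(self.seqs):
            raise FormatError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise FormatError(f"duplicate sequence ids: {dupes[:5]}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        bad = set("".join(self.seqs)) - ALLOWED_CHARS
        if bad:
            raise FormatError(f"invalid sequence characters: {sorted(bad)}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        ids, seqs = [], []
        for name, seq in pairs:
            ids.append(name)
            seqs.append(seq.upper())
        return cls(tuple(ids), tuple(seqs))

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def encoded(self) -> np.ndarray:
        """(n, length) uint8 matrix: A/C/G/T -> 0..3, missing -> 255."""
        raw = np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_sequences, self.length)
        return _ENCODE[raw]

    def subset(self, keep: Iterable[str]) -> "Alignment":
        keep = set(keep)
        pairs = [(i, s) for i, s in zip(self.ids, self.seqs) if i in keep]
        missing = keep - {i for i, _ in pairs}
        if missing:
            raise FormatError(f"ids not in alignment: {sorted(missing)[:5]}")
        return Alignment.from_pairs(pairs)


@dataclass(frozen=True)
class SpecimenTable:
    """Specimen metadata: morphospecies label (optional), area, locality.

    A missing morphospecies label marks a specimen that cannot be assigned
    morphologically (e.g. females without diagnostic characters); such
    specimens take part in clustering but are excluded from congruence
    scoring.
    """

    df: pd.DataFrame = field(repr=False)

    COLUMNS = ("specimen_id", "morphospecies", "area", "locality")

    def __post_init__(self) -> None:
        df = self.df
        for col in self.COLUMNS:
            if col not in df.columns:
                raise FormatError(f"specimen table missing column {col!r}")
        ids = df["specimen_id"]
        if ids.isna().any() or (ids.astype(str).str.len() == 0).any():
            raise FormatError("empty specimen_id")
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise FormatError(f"duplicate specimen_id: {dupes[:5]}")
        # A locality must belong to exactly one area.
        known = df.dropna(subset=["locality", "area"])
        n_areas = known.groupby("locality")["area"].nunique()
        bad = n_areas[n_areas > 1]
        if len(bad):
            raise ValidationError(
                f"locality mapped to multiple areas: {sorted(bad.index)[:5]}"
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str | None, str | None, str | None]],
    ) -> "SpecimenTable":
        df = pd.DataFrame(records, columns=list(cls.COLUMNS))
        return cls(df.astype(object).where(df.notna(), None))

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.df["specimen_id"])

    @property
    def areas(self) -> list[str]:
        return sorted(self.df["area"].dropna().unique())

    def assigned(self) -> pd.DataFrame:
        """Rows with a morphospecies label."""
        return self.df[self.df["morphospecies"].notna()]

    @property
    def n_unassigned(self) -> int:
        return int(self.df["morphospecies"].isna().sum())

    def morphospecies_partition(self) -> "Partition":
        """Reference partition from the morphospecies column (labelled rows)."""
        sub = self.assigned()
        return Partition(
            dict(zip(sub["specimen_id"], sub["morphospecies"])),
            source="morphospecies",
        )

    def ids_in_area(self, area: str) -> list[str]:
        return list(self.df.loc[self.df["area"] == area, "specimen_id"])


@dataclass(frozen=True)
class Partition:
    """Assignment of specimens to groups (a species hypothesis)."""

    assignment: Mapping[str, str]
    source: str = "external"

    def __post_init__(self) -> None:
        if any(g is None or g == "" for g in self.assignment.values()):
            raise ValidationError("empty group label in partition")

    def groups(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for sid, grp in self.assignment.items():
            out.setdefault(grp, set()).add(sid)
        return out

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def n_specimens(self) -> int:
        return len(self.assignment)

    def specimen_ids(self) -> set[str]:
        return set(self.assignment)

    def restrict(self, ids: Iterable[str]) -> "Partition":
        ids = set(ids)
        return Partition(
            {s: g for s, g in self.assignment.items() if s in ids},
            source=self.source,
        )

    def relabel_canonical(self) -> "Partition":
        """Rename every group after its lexicographically smallest member."""
        label = {g: min(members) for g, members in self.groups().items()}
        return Partition(
            {s: label[g] for s, g in self.assignment.items()}, source=self.source
        )


@dataclass(frozen=True)
class CommunityMatrix:
    """Species x site incidence (0/1) table."""

    incidence: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        inc = self.incidence
        if not inc.isin([0, 1]).all().all():
            raise ValidationError("incidence values must be 0/1")
        if (inc.sum(axis=1) == 0).any():
            absent = list(inc.index[inc.sum(axis=1) == 0])
            raise ValidationError(f"species with no presence: {absent[:5]}")

    @classmethod
    def from_occurrences(
        cls, occurrences: Iterable[tuple[str, str]]
    ) -> "CommunityMatrix":
        """Build from (species, site) pairs."""
        df = pd.DataFrame(occurrences, columns=["species", "site"])
        inc = (
            pd.crosstab(df["species"], df["site"]).clip(upper=1).astype(int)
        )
        inc = inc.sort_index(axis=0).sort_index(axis=1)
        return cls(inc)

    @property
    def sites(self) -> list[str]:
        return list(self.incidence.columns)

    @property
    def species(self) -> list[str]:
        return list(self.incidence.index)

    def richness(self) -> pd.Series:
        """Species count per site (alpha diversity)."""
        return self.incidence.sum(axis=0)


class UltrametricTree:
    """A rooted, binary, ultrametric tree with node ages (tips at age 0).

    Node ages are stored on every node as ``node.age``; ``read_newick``
    validates ultrametricity up to a relative tolerance before tip ages are
    snapped to exactly zero.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        root = tree.seed_node
        if root is None:
            raise FormatError("empty tree")
        self._validate_and_age()

    def _validate_and_age(self, rel_tol: float = 1e-6) -> None:
        tree = self.tree
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise FormatError("tree has unlabeled tips")
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate tip labels in tree")
        for node in tree.preorder_node_iter():
            if node.is_internal() and len(node.child_nodes()) != 2:
                raise ValidationError(
                    "polytomy (or unifurcation) in tree; resolve it upstream"
                )
            if node.parent_node is not None and node.edge.length is None:
                raise FormatError("tree edge without branch length")
        # Depth from root, then age = max_depth - depth.
        depth: dict[dendropy.Node, float] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                depth[node] = 0.0
            else:
                depth[node] = depth[node.parent_node] + node.edge.length
        tip_depths = np.array([depth[leaf] for leaf in tree.leaf_node_iter()])
        root_age = float(tip_depths.max())
        if root_age <= 0:
            raise ValidationError("tree has zero depth")
        dev = float(tip_depths.max() - tip_depths.min())
        if dev > rel_tol * root_age:
            raise ValidationError(
                f"tree is not ultrametric: tip depth spread {dev:.6g} exceeds "
                f"{rel_tol:g} x root age {root_age:.6g}"
            )
        for node in tree.preorder_node_iter():
            node.age = max(root_age - depth[node], 0.0)
        for leaf in tree.leaf_node_iter():
            leaf.age = 0.0
        self.root_age = root_age

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def internal_ages(self) -> np.ndarray:
        """Ages of internal nodes, descending (root first)."""
        ages = [n.age for n in self.tree.preorder_internal_node_iter()]
        return np.sort(np.asarray(ages, dtype=float))[::-1]

    def as_newick(self) -> str:
        # Re-derive branch lengths from ages so that snapped tips serialize
        # exactly ultrametric.
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = node.parent_node.age - node.age
        return (
            self.tree.as_string(schema="newick", suppress_rooting=True).strip()
        )


@dataclass(frozen=True)
class HaplotypeCollapse:
    """Bookkeeping of identical-haplotype removal.

    ``removed`` maps each kept representative to the ids of identical
    sequences that were dropped; entity membership can be re-expanded after
    delimitation.
    """

    kept_ids: tuple[str, ...]
    removed: Mapping[str, tuple[str, ...]]

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    def expand(self, partition: Partition) -> Partition:
        """Re-attach removed specimens to their representative's group."""
        assignment = dict(partition.assignment)
        for rep, dropped in self.removed.items():
            if rep not in assignment:
                raise ValidationError(
                    f"representative {rep!r} missing from partition"
                )
            for sid in dropped:
                assignment[sid] = assignment[rep]
        return Partition(assignment, source=partition.source)
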