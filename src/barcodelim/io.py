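"""Readers and writers for the pipeline's external formats.

FASTA for alignments (Biopython), newick for ultrametric trees (dendropy),
and tab-separated text for specimen tables, partitions and long-format
distance matrices.  Empty fields in delimited files denote absent values.
"""

from __future__ import annotations

import json
import logging
from os import PathLike
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    Alignment,
    FormatError,
    Partition,
    SpecimenTable,
    UltrametricTree,
)

logger = logging.getLogger(__name__)

PathType = str | PathLike


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathType) -> Alignment:
    """Read an aligned FASTA file; sequences are upper-cased on input."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment.from_pairs(records)


def write_fasta(alignment: Alignment, path: PathType) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(alignment.ids, alignment.seqs):
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Specimen tables


def read_specimen_table(path: PathType) -> SpecimenTable:
    """Read a tab-separated specimen table.

    Requires a header with at least ``specimen_id``; ``morphospecies``,
    ``area`` and ``locality`` are optional columns and empty cells mean
    "absent".
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "specimen_id" not in df.columns:
        raise FormatError("specimen table header must name 'specimen_id'")
    for col in SpecimenTable.COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df[list(SpecimenTable.COLUMNS)]
    df = df.astype(object).where(df != "", None)
    table = SpecimenTable(df)
    if table.n_unassigned:
        logger.info(
            "%d specimens without a morphospecies label (excluded from "
            "congruence scoring)",
            table.n_unassigned,
        )
    return table


def write_specimen_table(table: SpecimenTable, path: PathType) -> None:
    df = table.df.astype(object)
    df = df.where(df.notna(), "")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(path: PathType) -> UltrametricTree:
    """Read a single rooted ultrametric tree from a newick file."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return UltrametricTree(tree)


def read_newick_string(newick: str) -> UltrametricTree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return UltrametricTree(tree)


def write_newick(tree: UltrametricTree, path: PathType) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


# ---------------------------------------------------------------------------
# Partitions


def read_partition(path: PathType, source: str = "external") -> Partition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["specimen_id", "group"]:
        raise FormatError("partition file needs columns: specimen_id, group")
    if df["specimen_id"].duplicated().any():
        raise FormatError("duplicate specimen_id in partition file")
    return Partition(dict(zip(df["specimen_id"], df["group"])), source=source)


def write_partition(partition: Partition, path: PathType) -> None:
    rows = sorted(partition.assignment.items())
    df = pd.DataFrame(rows, columns=["specimen_id", "group"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Distance matrices (long format: id1 id2 distance n_sites)


def write_distance_long(dm, path: PathType) -> None:
    """Write the upper triangle of a DistanceMatrix as long-format TSV."""
    ids = dm.ids
    rows = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            d = dm.d[i, j]
            rows.append(
                (
                    ids[i],
                    ids[j],
                    "" if np.isnan(d) else f"{d:.10g}",
                    int(dm.n_sites[i, j]),
                )
            )
    pd.DataFrame(rows, columns=["id1", "id2", "distance", "n_sites"]).to_csv(
        path, sep="\t", index=False
    )


def read_distance_long(path: PathType):
    """Read a long-format distance TSV back into a DistanceMatrix."""
    from .distances import DistanceMatrix

    df = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
    ids = sorted(set(df["id1"]) | set(df["id2"]))
    idx = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    d = np.zeros((n, n))
    ns = np.zeros((n, n), dtype=int)
    for row in df.itertuples(index=False):
        i, j = idx[row.id1], idx[row.id2]
        val = float(row.distance) if pd.notna(row.distance) else np.nan
        d[i, j] = d[j, i] = val
        ns[i, j] = ns[j, i] = int(row.n_sites)
    return DistanceMatrix(tuple(ids), d, ns)


# ---------------------------------------------------------------------------
# Run-configuration echo


def write_config_json(config: dict, path: PathType) -> None:
    Path(path).write_text(json.dumps(config, indent=2, default=str) + "\n")
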