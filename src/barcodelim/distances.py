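"""Uncorrected p-distances with pairwise deletion, and divergence summaries.

The p-distance between two aligned sequences is the fraction of mismatching
positions among the positions where *both* sequences carry an unambiguous
base (A/C/G/T).  Gaps, N, ? and IUPAC ambiguity codes are deleted pairwise.
A pair with no comparable positions has an *undefined* distance (NaN), never
zero.  Model-corrected distances (K2P etc.) are deliberately not offered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Alignment, AlignmentError, MISSING_CODE, Partition

logger = logging.getLogger(__name__)


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Uncorrected p-distance between two aligned sequences.

    Returns ``(distance, n_compared)``; the distance is ``nan`` when no
    position is comparable.
    """
    if len(seq_a) != len(seq_b):
        raise AlignmentError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    aln = Alignment.from_pairs([("a", seq_a), ("b", seq_b)])
    enc = aln.encoded()
    both = (enc[0] != MISSING_CODE) & (enc[1] != MISSING_CODE)
    n_compared = int(both.sum())
    if n_compared == 0:
        return math.nan, 0
    mismatches = int(((enc[0] != enc[1]) & both).sum())
    return mismatches / n_compared, n_compared


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise p-distance matrix with compared-site counts."""

    ids: tuple[str, ...]
    d: np.ndarray = field(repr=False)
    n_sites: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.n_sites.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise ValueError("distance matrix not symmetric")
        finite = self.d[~np.isnan(self.d)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("distances outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(np.isnan(self.d[iu]).sum())

    def index_of(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def submatrix(self, keep_ids) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in keep_ids]
        return DistanceMatrix(
            tuple(keep_ids),
            self.d[np.ix_(idx, idx)].copy(),
            self.n_sites[np.ix_(idx, idx)].copy(),
        )

    def max_defined(self) -> float:
        iu = np.triu_indices(self.n, k=1)
        vals = self.d[iu]
        return float(np.nanmax(vals)) if vals.size else 0.0


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All-pairs p-distances with pairwise deletion (vectorized)."""
    if alignment.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    enc = alignment.encoded()
    valid = enc != MISSING_CODE
    n = alignment.n_sequences
    d = np.zeros((n, n))
    ns = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(ns, valid.sum(axis=1))
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        nc = both.sum(axis=1)
        nd = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(nc > 0, nd / np.maximum(nc, 1), np.nan)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
        ns[i, i + 1 :] = nc
        ns[i + 1 :, i] = nc
    dm = DistanceMatrix(tuple(alignment.ids), d, ns)
    if dm.n_undefined_pairs:
        logger.warning(
            "%d sequence pairs share no comparable sites (distance undefined)",
            dm.n_undefined_pairs,
        )
    return dm


@dataclass(frozen=True)
class DivergenceSummary:
    """Per-species and global intra/interspecific divergence figures.

    ``per_species`` has one row per group with columns ``n_specimens``,
    ``mean_intra``, ``max_intra`` (NaN for singletons, reported as "n/a").
    Global means are means over specimen pairs, not species-pair averages.
    """

    per_species: pd.DataFrame = field(repr=False)
    intra_mean: float
    intra_min: float
    intra_max: float
    inter_mean: float
    inter_min: float
    inter_max: float
    n_intra_pairs: int
    n_inter_pairs: int
    n_undefined_pairs: int

    def report(self) -> pd.DataFrame:
        """Percent-scale per-species table (2 decimals; n/a for singletons)."""
        out = self.per_species.copy()
        for col in ("mean_intra", "max_intra"):
            out[col] = [
                "n/a" if np.isnan(v) else f"{100 * v:.2f}" for v in out[col]
            ]
        return out


def divergence_summary(
    dm: DistanceMatrix, partition: Partition
) -> DivergenceSummary:
    """Split pairwise distances into intra- and interspecific components.

    Specimens not assigned in ``partition`` are excluded; undefined pairs are
    excluded from every mean with a logged count.
    """
    assigned = [s for s in dm.ids if s in partition.assignment]
    dropped = dm.n - len(assigned)
    if dropped:
        logger.info("%d specimens unassigned in partition: excluded", dropped)
    sub = dm.submatrix(assigned) if dropped else dm
    labels = np.array([partition.assignment[s] for s in sub.ids])
    iu = np.triu_indices(sub.n, k=1)
    vals = sub.d[iu]
    same = labels[iu[0]] == labels[iu[1]]
    defined = ~np.isnan(vals)
    n_undef = int((~defined).sum())
    if n_undef:
        logger.warning("%d undefined pairs excluded from summary", n_undef)

    intra = vals[same & defined]
    inter = vals[~same & defined]

    rows = {}
    for grp in sorted(set(labels)):
        members = np.where(labels == grp)[0]
        block = sub.d[np.ix_(members, members)]
        tri = block[np.triu_indices(len(members), k=1)]
        tri = tri[~np.isnan(tri)]
        rows[grp] = {
            "n_specimens": len(members),
            "mean_intra": float(tri.mean()) if tri.size else math.nan,
            "max_intra": float(tri.max()) if tri.size else math.nan,
        }
    per_species = pd.DataFrame.from_dict(rows, orient="index")
    per_species.index.name = "species"

    def _stats(x: np.ndarray) -> tuple[float, float, float]:
        if x.size == 0:
            return math.nan, math.nan, math.nan
        return float(x.mean()), float(x.min()), float(x.max())

    i_mean, i_min, i_max = _stats(intra)
    e_mean, e_min, e_max = _stats(inter)
    return DivergenceSummary(
        per_species=per_species,
        intra_mean=i_mean,
        intra_min=i_min,
        intra_max=i_max,
        inter_mean=e_mean,
        inter_min=e_min,
        inter_max=e_max,
        n_intra_pairs=int(intra.size),
        n_inter_pairs=int(inter.size),
        n_undefined_pairs=n_undef,
    )


def flag_divergent_species(
    summary: DivergenceSummary,
    cutoff: float = 0.03,
    statistic: str = "mean",
) -> list[str]:
    """Species whose intraspecific divergence strictly exceeds ``cutoff``.

    ``statistic`` selects the per-species figure: ``"mean"`` (default,
    average intraspecific p-distance) or ``"max"``.  Sorted by descending
    divergence; candidates for cryptic-species scrutiny.
    """
    col = {"mean": "mean_intra", "max": "max_intra"}[statistic]
    ps = summary.per_species
    flagged = ps[ps[col] > cutoff].sort_values(col, ascending=False)
    return [str(label) for label in flagged.index]
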