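"""Congruence of a candidate partition against reference morphospecies.

Each candidate group is classified as *perfect* (exactly all members of one
reference species), *lumped* (members of two or more species) or *split*
(members of only part of one species); lumped takes precedence, so the three
counts always partition the groups.  From the counts:

    agreement [%]          = 100 * n_groups  / n_species
    taxonomic accuracy [%] = 100 * n_perfect / n_species

Agreement above 100% signals overestimation of species diversity.
Specimens without a reference label are dropped from both partitions before
scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .model import Partition, ValidationError

logger = logging.getLogger(__name__)

PERFECT = "perfect"
LUMPED = "lumped"
SPLIT = "split"


@dataclass(frozen=True)
class CongruenceReport:
    """One row of the congruence table."""

    n_species: int
    n_groups: int
    n_perfect: int
    n_lumped: int
    n_split: int
    #: number of reference species affected by splitting (the split count
    #: above counts candidate groups, not species)
    n_split_species: int = 0

    def __post_init__(self) -> None:
        if self.n_species <= 0:
            raise ValidationError("empty reference partition")
        if self.n_perfect + self.n_lumped + self.n_split != self.n_groups:
            raise ValidationError(
                "class counts do not partition the candidate groups"
            )

    @property
    def agreement_pct(self) -> float:
        return 100.0 * self.n_groups / self.n_species

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.n_perfect / self.n_species

    @property
    def overestimation_pct(self) -> float:
        """Agreement minus 100 (negative = underestimation)."""
        return self.agreement_pct - 100.0


def classify_groups(
    candidate: Partition, reference: Partition
) -> dict[str, str]:
    """Classify each candidate group as perfect / lumped / split."""
    ref_ids = reference.specimen_ids()
    cand_ids = candidate.specimen_ids()
    unscored = cand_ids - ref_ids
    if unscored:
        logger.info(
            "%d specimens absent from reference dropped before scoring",
            len(unscored),
        )
        candidate = candidate.restrict(ref_ids)
        cand_ids = candidate.specimen_ids()
    if ref_ids - cand_ids:
        raise ValidationError(
            f"candidate does not cover {len(ref_ids - cand_ids)} reference "
            "specimens"
        )
    ref_groups = reference.groups()
    ref_of = reference.assignment
    classes: dict[str, str] = {}
    for label, members in candidate.groups().items():
        species = {ref_of[s] for s in members}
        if len(species) > 1:
            classes[label] = LUMPED
        else:
            (sp,) = species
            classes[label] = (
                PERFECT if members == ref_groups[sp] else SPLIT
            )
    return classes


def congruence_report(
    candidate: Partition, reference: Partition
) -> CongruenceReport:
    """Score a candidate partition against the reference morphospecies."""
    if reference.n_specimens == 0:
        raise ValidationError("empty reference partition")
    classes = classify_groups(candidate, reference)
    candidate = candidate.restrict(reference.specimen_ids())
    ref_of = reference.assignment
    split_species = {
        ref_of[next(iter(members))]
        for label, members in candidate.groups().items()
        if classes[label] == SPLIT
    }
    counts = {PERFECT: 0, LUMPED: 0, SPLIT: 0}
    for cls in classes.values():
        counts[cls] += 1
    return CongruenceReport(
        n_species=reference.n_groups,
        n_groups=len(classes),
        n_perfect=counts[PERFECT],
        n_lumped=counts[LUMPED],
        n_split=counts[SPLIT],
        n_split_species=len(split_species),
    )


#: Column order of the tabular congruence report.
TABLE_COLUMNS = [
    "dataset",
    "n_morphospecies",
    "n_clusters",
    "agreement_pct",
    "n_perfect",
    "accuracy_pct",
    "n_lumped",
    "n_split",
]


def table2_report(
    datasets: list[tuple[str, Partition, Partition]],
    decimals: int = 1,
) -> pd.DataFrame:
    """One congruence row per (name, candidate, reference) dataset.

    Percentages are rounded to ``decimals`` places (1 by default for the
    human-readable table; use 2 for machine output).
    """
    rows = []
    for name, candidate, reference in datasets:
        rep = congruence_report(candidate, reference)
        rows.append(
            {
                "dataset": name,
                "n_morphospecies": rep.n_species,
                "n_clusters": rep.n_groups,
                "agreement_pct": round(rep.agreement_pct, decimals),
                "n_perfect": rep.n_perfect,
                "accuracy_pct": round(rep.accuracy_pct, decimals),
                "n_lumped": rep.n_lumped,
                "n_split": rep.n_split,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
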