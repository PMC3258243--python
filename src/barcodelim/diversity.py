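"""Beta-diversity (Sørensen) and the regional-vs-local clustering comparison.

The Sørensen similarity of two sites with A and B species of which C are
shared is QS = 2C / (A + B).  The regional/local comparison clusters each
area's sequences separately and the pooled dataset as a whole, expresses
agreement and taxonomic accuracy as percentages of each area's own
morphospecies count, and asks at every threshold whether the pooled value
falls inside the 95% confidence interval built from the per-area values.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import Alignment, CommunityMatrix, SpecimenTable, ValidationError
from .clustering import cluster_at_threshold
from .congruence import congruence_report
from .distances import DistanceMatrix, distance_matrix

logger = logging.getLogger(__name__)


def sorensen(a: int, b: int, c: int) -> float:
    """Sørensen similarity QS = 2C/(A+B) for sites with A and B species, C shared."""
    if a < 1 or b < 1:
        raise ValidationError("each site needs at least one species")
    if c > min(a, b):
        raise ValidationError(f"shared count {c} exceeds min({a}, {b})")
    return 2.0 * c / (a + b)


@dataclass(frozen=True)
class SorensenMatrix:
    """Pairwise site similarity: species counts, shared counts and QS."""

    sites: tuple[str, ...]
    richness: pd.Series = field(repr=False)   #: species per site
    shared: pd.DataFrame = field(repr=False)  #: pairwise shared species C
    qs: pd.DataFrame = field(repr=False)      #: pairwise Sørensen index
    mean_qs: float

    def report(self, decimals: int = 2) -> pd.DataFrame:
        """Counts in the upper triangle, QS (rounded) in the lower."""
        n = len(self.sites)
        out = pd.DataFrame("", index=self.sites, columns=self.sites)
        for i, j in itertools.combinations(range(n), 2):
            si, sj = self.sites[i], self.sites[j]
            out.loc[si, sj] = str(int(self.shared.loc[si, sj]))
            q = self.qs.loc[sj, si]
            out.loc[sj, si] = "" if math.isnan(q) else f"{q:.{decimals}f}"
        out.insert(0, "n_species", [int(self.richness[s]) for s in self.sites])
        return out


def sorensen_matrix(cm: CommunityMatrix) -> SorensenMatrix:
    """Pairwise Sørensen similarities from an incidence matrix."""
    sites = cm.sites
    if len(sites) < 2:
        raise ValidationError("need at least 2 sites")
    inc = cm.incidence.to_numpy()
    richness = cm.richness()
    shared_np = inc.T @ inc
    shared = pd.DataFrame(shared_np, index=sites, columns=sites)
    qs = pd.DataFrame(np.nan, index=sites, columns=sites)
    vals = []
    for i, j in itertools.combinations(range(len(sites)), 2):
        a, b = int(richness.iloc[i]), int(richness.iloc[j])
        if a == 0 or b == 0:
            logger.warning(
                "site %s has no species: pair undefined", sites[i if a == 0 else j]
            )
            continue
        q = sorensen(a, b, int(shared_np[i, j]))
        qs.iloc[i, j] = qs.iloc[j, i] = q
        vals.append(q)
    return SorensenMatrix(
        sites=tuple(sites),
        richness=richness,
        shared=shared,
        qs=qs,
        mean_qs=float(np.mean(vals)) if vals else math.nan,
    )


def occupancy_summary(cm: CommunityMatrix) -> pd.DataFrame:
    """Histogram of species by the number of sites they occupy."""
    k = cm.incidence.sum(axis=1)
    n_sites = len(cm.sites)
    counts = k.value_counts().reindex(range(1, n_sites + 1), fill_value=0)
    out = pd.DataFrame(
        {
            "n_sites": counts.index,
            "n_species": counts.to_numpy(),
        }
    )
    out["pct_species"] = 100.0 * out["n_species"] / len(cm.species)
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class CIComparison:
    """Pooled value vs a 95% CI on the mean of per-area values."""

    mean: float
    lower: float
    upper: float
    outside: bool


def ci_compare(
    per_area_values: list[float] | np.ndarray,
    pooled_value: float,
    method: str = "t",
) -> CIComparison:
    """Flag the pooled value if strictly outside the 95% CI of area values.

    The CI is mean ± q * sd/sqrt(n) with q the Student-t 97.5% quantile on
    n-1 df (``method="normal"`` uses 1.96 instead).  A zero-variance sample
    degenerates to a point interval.
    """
    vals = np.asarray(per_area_values, dtype=float)
    if len(vals) < 2:
        raise ValidationError("need at least 2 area values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        return CIComparison(mean, mean, mean, pooled_value != mean)
    if method == "t":
        q = float(stats.t.ppf(0.975, df=len(vals) - 1))
    elif method == "normal":
        q = float(stats.norm.ppf(0.975))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    half = q * sd / math.sqrt(len(vals))
    lower, upper = mean - half, mean + half
    return CIComparison(
        mean, lower, upper, bool(pooled_value < lower or pooled_value > upper)
    )


@dataclass(frozen=True)
class SweepComparison:
    """Regional-vs-local clustering comparison across thresholds."""

    table: pd.DataFrame = field(repr=False)      #: one row per threshold
    per_area: pd.DataFrame = field(repr=False)   #: long per-area values
    areas: tuple[str, ...]


def regional_local_sweep(
    alignment: Alignment,
    specimens: SpecimenTable,
    thresholds: list[float] | None = None,
    dm: DistanceMatrix | None = None,
    ci_method: str = "t",
) -> SweepComparison:
    """Compare per-area and pooled clustering congruence across thresholds.

    For each area, sequences are clustered on their own and scored against
    that area's morphospecies; the pooled dataset is clustered whole.
    Agreement and accuracy are relative to each dataset's own morphospecies
    count.  Areas with fewer than 2 labelled specimens are excluded with a
    warning.
    """
    if thresholds is None:
        thresholds = [t / 100 for t in range(1, 13)]
    if dm is None:
        dm = distance_matrix(alignment)
    reference = specimens.morphospecies_partition()
    scored_ids = [s for s in dm.ids if s in reference.assignment]

    areas = []
    for area in specimens.areas:
        ids = [s for s in specimens.ids_in_area(area) if s in reference.assignment]
        if len(ids) < 2:
            logger.warning("area %s has <2 labelled specimens: excluded", area)
            continue
        areas.append((area, ids))

    rows_long = []
    rows_wide = []
    pooled_dm = dm.submatrix(scored_ids)
    area_dms = {a: dm.submatrix(ids) for a, ids in areas}
    for t in thresholds:
        pooled = congruence_report(
            cluster_at_threshold(pooled_dm, t).partition, reference
        )
        area_vals = {"agreement": [], "accuracy": []}
        for area, ids in areas:
            rep = congruence_report(
                cluster_at_threshold(area_dms[area], t).partition,
                reference.restrict(ids),
            )
            area_vals["agreement"].append(rep.agreement_pct)
            area_vals["accuracy"].append(rep.accuracy_pct)
            rows_long.append(
                {
                    "threshold_pct": 100 * t,
                    "area": area,
                    "agreement_pct": rep.agreement_pct,
                    "accuracy_pct": rep.accuracy_pct,
                }
            )
        row = {"threshold_pct": 100 * t}
        for metric, pooled_val in (
            ("agreement", pooled.agreement_pct),
            ("accuracy", pooled.accuracy_pct),
        ):
            ci = ci_compare(area_vals[metric], pooled_val, method=ci_method)
            row.update(
                {
                    f"{metric}_pooled": pooled_val,
                    f"{metric}_area_mean": ci.mean,
                    f"{metric}_ci_lower": ci.lower,
                    f"{metric}_ci_upper": ci.upper,
                    f"{metric}_outside": ci.outside,
                }
            )
        rows_wide.append(row)
    return SweepComparison(
        table=pd.DataFrame(rows_wide),
        per_area=pd.DataFrame(rows_long),
        areas=tuple(a for a, _ in areas),
    )
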