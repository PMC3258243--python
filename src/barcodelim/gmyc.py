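"""Single-threshold GMYC species delimitation on an ultrametric tree.

The general mixed Yule coalescent (GMYC) model assumes that, on a chronogram,
branching events older than a threshold age T reflect speciation (a Yule
process on between-species lineages) while events younger than T reflect
coalescence within species.  Between successive branching events the waiting
time is exponential with total rate

    b_i = lambda1 * n_div_i**p1 + lambda2 * sum_j (n_ji * (n_ji - 1))**p2

where ``n_div_i`` counts lineages that originate above T during interval i,
and ``n_ji`` counts the lineages of entity j (the subtree hanging below one
lineage crossing T).  The scaling exponents p1 and p2 are constrained to
[0, 10].  The log-likelihood is sum_i [log b_i - b_i * x_i] over the
inter-event intervals with waiting times x_i.

Fitting maximizes this likelihood over candidate thresholds placed at
midpoints between consecutive node ages (plus one candidate above the root,
the null configuration); the lineages crossing the best threshold are the
delimited *entities*.  The fit is compared to a single-process null model
(one rate, one exponent over the whole tree) by a likelihood-ratio test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .model import HaplotypeCollapse, Partition, UltrametricTree, ValidationError

logger = logging.getLogger(__name__)

#: Bounds for the scaling exponents p1, p2.
P_BOUNDS = (0.0, 10.0)
#: Bounds for log rate parameters.
LOG_RATE_BOUNDS = (-30.0, 15.0)
#: Candidates within this many log-likelihood units of the maximum define
#: the entity-count confidence set.
CONFIDENCE_DELTA = 2.0


@dataclass(frozen=True)
class BranchingSchedule:
    """Event times and lineage bookkeeping extracted from a chronogram.

    ``ages`` holds the internal-node ages in descending order (root first);
    ``x`` the waiting times between successive events, the last one running
    to the present; ``parent`` maps each event to the index of its parent
    event (-1 for the root).  Exact age ties are broken by a deterministic
    jitter of 1e-9 x root age so that events are strictly ordered.
    """

    ages: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)
    parent: np.ndarray = field(repr=False)
    tip_parent: np.ndarray = field(repr=False)
    tip_labels: tuple[str, ...]

    @property
    def n_events(self) -> int:
        return len(self.ages)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root_age(self) -> float:
        return float(self.ages[0])


def branching_schedule(tree: UltrametricTree) -> BranchingSchedule:
    """Extract the ordered branching times and topology bookkeeping."""
    if tree.n_tips < 3:
        raise ValidationError("GMYC needs a tree with at least 3 tips")
    internal = list(tree.tree.preorder_internal_node_iter())
    ages = np.array([n.age for n in internal], dtype=float)
    # Deterministic tie-jitter, indexed by preorder position so a parent in a
    # tie group stays strictly older than its descendants.
    if len(np.unique(ages)) < len(ages):
        eps = 1e-9 * float(ages.max())
        order = {}
        for k, a in enumerate(ages):
            order.setdefault(a, []).append(k)
        for tied in order.values():
            if len(tied) > 1:
                logger.info("breaking %d-way age tie with jitter", len(tied))
                for rank, k in enumerate(tied):
                    ages[k] += (len(tied) - 1 - rank) * eps
    sort = np.argsort(-ages)
    ages = ages[sort]
    pos = {id(internal[k]): i for i, k in enumerate(sort)}
    parent = np.empty(len(internal), dtype=np.int64)
    for k, node in enumerate(internal):
        p = node.parent_node
        parent[pos[id(node)]] = -1 if p is None else pos[id(p)]
    leaves = list(tree.tree.leaf_node_iter())
    tip_parent = np.array(
        [pos[id(leaf.parent_node)] for leaf in leaves], dtype=np.int64
    )
    tip_labels = tuple(leaf.taxon.label for leaf in leaves)
    x = np.diff(np.append(ages, 0.0)) * -1.0
    return BranchingSchedule(
        ages=ages, x=x, parent=parent, tip_parent=tip_parent,
        tip_labels=tip_labels,
    )


# ---------------------------------------------------------------------------
# Likelihood


def _candidate_arrays(
    schedule: BranchingSchedule, m: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-interval bookkeeping for the candidate with ``m`` events above T.

    Returns ``(ndiv, old_c, new_c)``: the diversification lineage count per
    interval, and the entity pair-count n(n-1) replaced at each below-T
    event (cumulative differences of powers of these give the coalescent
    rate term for any exponent p2).
    """
    e = schedule.n_events
    ndiv = np.minimum(np.arange(e) + 2, m + 1).astype(float)
    old_c = np.zeros(e)
    new_c = np.zeros(e)
    ent = np.empty(e, dtype=np.int64)
    counts: dict[int, int] = {}
    for k in range(m, e):
        p = schedule.parent[k]
        ent[k] = k if p < m else ent[p]
        n = counts.get(ent[k], 1)
        old_c[k] = n * (n - 1)
        new_c[k] = (n + 1) * n
        counts[ent[k]] = n + 1
    return ndiv, old_c, new_c


def _loglik_arrays(
    ndiv: np.ndarray,
    old_c: np.ndarray,
    new_c: np.ndarray,
    x: np.ndarray,
    lam1: float,
    p1: float,
    lam2: float,
    p2: float,
) -> float:
    # 0**p2 must contribute 0 even at p2 == 0 (a one-lineage entity has no
    # coalescent rate), hence the explicit masking.
    po = np.zeros_like(old_c)
    pn = np.zeros_like(new_c)
    po[old_c > 0] = old_c[old_c > 0] ** p2
    pn[new_c > 0] = new_c[new_c > 0] ** p2
    s = np.cumsum(pn - po)
    b = lam1 * np.power(ndiv, p1) + lam2 * s
    if np.any(b <= 0) or not np.all(np.isfinite(b)):
        return -np.inf
    return float(np.sum(np.log(b)) - np.dot(b, x))


def gmyc_loglik(
    schedule: BranchingSchedule,
    threshold_age: float,
    lam1: float,
    p1: float,
    lam2: float,
    p2: float,
) -> float:
    """Mixed Yule/coalescent log-likelihood at a given threshold age.

    With ``threshold_age`` at or above the root the expression reduces to
    the pure single-process (coalescent) form in ``lam2, p2``.
    """
    if threshold_age <= 0:
        raise ValueError("threshold age must be positive")
    if lam1 <= 0 or lam2 <= 0:
        raise ValueError("rates must be positive")
    for p in (p1, p2):
        if not P_BOUNDS[0] <= p <= P_BOUNDS[1]:
            raise ValueError(f"scaling exponent {p} outside {P_BOUNDS}")
    m = int(np.sum(schedule.ages > threshold_age))
    ndiv, old_c, new_c = _candidate_arrays(schedule, m)
    return _loglik_arrays(ndiv, old_c, new_c, schedule.x, lam1, p1, lam2, p2)


def _fit_null(schedule: BranchingSchedule) -> tuple[float, float, float]:
    """Single-process null model b_i = lam * (n_i (n_i - 1))**p.

    The rate is profiled analytically; the exponent is optimized on [0, 10].
    Returns (lnL, lam_hat, p_hat).
    """
    e = schedule.n_events
    n = np.arange(e) + 2.0
    base = n * (n - 1.0)
    x = schedule.x

    def profile_neg(p: float) -> float:
        bp = np.power(base, p)
        denom = float(np.dot(bp, x))
        lam = e / denom
        return -(float(np.sum(np.log(lam * bp))) - lam * denom)

    res = minimize_scalar(
        profile_neg, bounds=P_BOUNDS, method="bounded",
        options={"xatol": 1e-10},
    )
    p_hat = float(res.x)
    bp = np.power(base, p_hat)
    lam_hat = e / float(np.dot(bp, x))
    return -float(res.fun), lam_hat, p_hat


def _optimize_candidate(
    schedule: BranchingSchedule,
    m: int,
    extra_starts: list[np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Maximize the likelihood over (lam1, p1, lam2, p2) for one candidate.

    Multi-start bounded quasi-Newton in (log lam1, p1, log lam2, p2):
    three deterministic starts at p = 1 (moment-matched rates), 0.5 and 2.
    """
    ndiv, old_c, new_c = _candidate_arrays(schedule, m)
    x = schedule.x
    e = schedule.n_events
    log_ndiv = np.log(ndiv)
    mask_o, mask_n = old_c > 0, new_c > 0
    log_old = np.where(mask_o, np.log(np.where(mask_o, old_c, 1.0)), 0.0)
    log_new = np.where(mask_n, np.log(np.where(mask_n, new_c, 1.0)), 0.0)

    def neg(theta: np.ndarray) -> tuple[float, np.ndarray]:
        lam1, p1, lam2, p2 = (
            np.exp(theta[0]), theta[1], np.exp(theta[2]), theta[3],
        )
        a = np.exp(p1 * log_ndiv)
        po = np.where(mask_o, np.exp(p2 * log_old), 0.0)
        pn = np.where(mask_n, np.exp(p2 * log_new), 0.0)
        s = np.cumsum(pn - po)
        b = lam1 * a + lam2 * s
        if np.any(b <= 0) or not np.all(np.isfinite(b)):
            return 1e12, np.zeros(4)
        w = 1.0 / b - x  # d lnL / d b_i
        # partials of b wrt (log lam1, p1, log lam2, p2)
        ds_dp2 = np.cumsum(pn * log_new - po * log_old)
        grad = -np.array(
            [
                np.dot(w, lam1 * a),
                np.dot(w, lam1 * a * log_ndiv),
                np.dot(w, lam2 * s),
                np.dot(w, lam2 * ds_dp2),
            ]
        )
        val = float(np.sum(np.log(b)) - np.dot(b, x))
        return -val, grad

    def moment_start(p: float) -> np.ndarray:
        a = np.power(ndiv, p)
        po = np.where(old_c > 0, old_c**p, 0.0)
        pn = np.where(new_c > 0, new_c**p, 0.0)
        s = np.cumsum(pn - po)
        lam1 = (m + 0.5) / max(float(np.dot(a, x)), 1e-12)
        denom = max(float(np.dot(s, x)), 1e-12)
        lam2 = (e - m + 0.5) / denom
        return np.array([np.log(lam1), p, np.log(lam2), p])

    starts = [moment_start(1.0), moment_start(0.5), moment_start(2.0)]
    if extra_starts:
        starts.extend(extra_starts)
    bounds = [LOG_RATE_BOUNDS, P_BOUNDS, LOG_RATE_BOUNDS, P_BOUNDS]
    best_val, best_theta = -np.inf, None
    for theta0 in starts:
        theta0 = np.clip(
            theta0,
            [b[0] for b in bounds],
            [b[1] for b in bounds],
        )
        try:
            res = minimize(
                neg, theta0, method="L-BFGS-B", bounds=bounds, jac=True,
                options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 200},
            )
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if np.isfinite(res.fun) and -res.fun > best_val:
            best_val, best_theta = -float(res.fun), res.x
    if best_theta is None:
        raise RuntimeError(f"optimizer failed for candidate m={m}")
    return best_val, best_theta


@dataclass(frozen=True)
class GMYCResult:
    """Fitted single-threshold GMYC model and delimited entities."""

    threshold_age: float
    lambda1: float
    p1: float
    lambda2: float
    p2: float
    lnl_max: float
    lnl_null: float
    lr: float
    p_value: float          #: chi-square, df=3 (parameter counting)
    p_value_df2: float      #: chi-square, df=2 alternative convention
    entities: Partition
    n_entities: int
    n_singletons: int
    entity_ci: tuple[int, int]
    #: per-candidate profile: threshold age, lnL, entity count
    profile: pd.DataFrame = field(repr=False)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def params_dict(self) -> dict:
        return {
            "threshold_age": self.threshold_age,
            "lambda1": self.lambda1,
            "p1": self.p1,
            "lambda2": self.lambda2,
            "p2": self.p2,
            "lnl_max": self.lnl_max,
            "lnl_null": self.lnl_null,
            "lr": self.lr,
            "p_value_df3": self.p_value,
            "p_value_df2": self.p_value_df2,
            "n_entities": self.n_entities,
            "n_singletons": self.n_singletons,
            "entity_ci": list(self.entity_ci),
        }


def _entities_for_candidate(
    schedule: BranchingSchedule, m: int
) -> Partition:
    """Group tips by the lineage crossing the candidate threshold."""
    e = schedule.n_events
    ent = np.empty(e, dtype=np.int64)
    for k in range(m, e):
        p = schedule.parent[k]
        ent[k] = k if p < m else ent[p]
    assignment: dict[str, int] = {}
    for t, label in enumerate(schedule.tip_labels):
        q = schedule.tip_parent[t]
        # Tips whose parent node is above the threshold are singletons.
        assignment[label] = -(t + 1) if q < m else int(ent[q])
    groups: dict[int, list[str]] = {}
    for label, g in assignment.items():
        groups.setdefault(g, []).append(label)
    named = {}
    for members in groups.values():
        name = min(members)
        for sid in members:
            named[sid] = name
    return Partition(named, source="gmyc")


def gmyc_fit(tree: UltrametricTree, method: str = "single") -> GMYCResult:
    """Fit the single-threshold GMYC model and delimit entities.

    Candidate thresholds sit at midpoints between consecutive node ages plus
    one candidate above the root (the null configuration).  The entity-count
    confidence set collects candidates within 2 log-likelihood units of the
    maximum.  Identical haplotypes should be collapsed beforehand; zero-age
    internal nodes trigger a warning.
    """
    if method != "single":
        raise ValueError("only the single-threshold method is implemented")
    schedule = branching_schedule(tree)
    if np.any(schedule.ages < 1e-12 * schedule.root_age):
        logger.warning(
            "near-zero internal node ages: identical haplotypes should be "
            "collapsed before GMYC"
        )
    ages = schedule.ages
    e = schedule.n_events
    lnl_null, lam_null, p_null = _fit_null(schedule)

    # Candidate m = number of events above the threshold.
    candidates: list[tuple[int, float]] = [(0, ages[0] * 1.5)]
    candidates += [
        (m, 0.5 * (ages[m - 1] + ages[m])) for m in range(1, e)
    ]
    null_start = np.array(
        [LOG_RATE_BOUNDS[0], 1.0, np.log(lam_null), p_null]
    )
    results = []
    for m, t_age in candidates:
        extra = [null_start] if m == 0 else None
        try:
            lnl, theta = _optimize_candidate(schedule, m, extra_starts=extra)
        except RuntimeError as err:
            logger.warning("skipping candidate m=%d: %s", m, err)
            continue
        results.append((m, t_age, lnl, theta))
    if not results:
        raise RuntimeError("all GMYC candidates failed to optimize")

    lnls = np.array([r[2] for r in results])
    best = int(np.argmax(lnls))
    m_star, t_star, lnl_max, theta = results[best]
    lnl_max = max(lnl_max, lnl_null)  # nested models; guard roundoff
    in_ci = lnls >= lnl_max - CONFIDENCE_DELTA
    ci_counts = [results[i][0] + 1 for i in np.where(in_ci)[0]]
    entities = _entities_for_candidate(schedule, m_star)
    sizes = [len(v) for v in entities.groups().values()]
    lr = max(2.0 * (lnl_max - lnl_null), 0.0)
    profile = pd.DataFrame(
        {
            "threshold_age": [r[1] for r in results],
            "lnl": lnls,
            "n_entities": [r[0] + 1 for r in results],
        }
    )
    return GMYCResult(
        threshold_age=float(t_star),
        lambda1=float(np.exp(theta[0])),
        p1=float(theta[1]),
        lambda2=float(np.exp(theta[2])),
        p2=float(theta[3]),
        lnl_max=float(lnl_max),
        lnl_null=float(lnl_null),
        lr=float(lr),
        p_value=float(chi2.sf(lr, df=3)),
        p_value_df2=float(chi2.sf(lr, df=2)),
        entities=entities,
        n_entities=m_star + 1,
        n_singletons=int(sum(1 for s in sizes if s == 1)),
        entity_ci=(int(min(ci_counts)), int(max(ci_counts))),
        profile=profile,
    )


def expand_entities(
    result: GMYCResult, collapse: HaplotypeCollapse
) -> Partition:
    """Re-attach collapsed haplotypes to their representative's entity."""
    return collapse.expand(result.entities)
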