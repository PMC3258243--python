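"""Synthetic barcode communities with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a hyperdiverse arthropod community of a few hundred species with a
deep barcoding gap (mean intraspecific p-distance ~1.3%, interspecific
~19.8% within 12-24%), 3-4 sequenced specimens per species, strong
geographic turnover across seven areas, occasional cryptic (lumped) and
oversplit morphospecies labels, and chronograms generated under the mixed
Yule/coalescent process (pure-birth species tree, neutral coalescent
genealogies within species).  Every stochastic choice flows from one seeded
generator, and the injected labelling errors are recorded so that expected
congruence metrics are computable in closed form.

Sequence evolution is a uniform random-site substitution process calibrated
to hit target Hamming-distance bands; it makes no attempt at rate
heterogeneity or codon structure, because distances -- not phylogenetic
realism -- drive every downstream analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .model import Alignment, CommunityMatrix, Partition, SpecimenTable
from .congruence import CongruenceReport
from .io import read_newick_string
from .model import UltrametricTree

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: Area occupancy proportions for k = 1..5 areas, from the observed shape of
#: a hyperdiverse montane community (the vast majority of species local to a
#: single area).
DEFAULT_OCCUPANCY = (259, 10, 2, 0, 1)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the sequence/community generator."""

    n_species: int = 270
    specimens_per_species: tuple[int, ...] = (3, 4)
    seq_length: int = 658
    #: target mean pairwise intraspecific p-distance
    intra_mean: float = 0.0128
    #: target mean and range of pairwise interspecific p-distances
    inter_mean: float = 0.198
    inter_range: tuple[float, float] = (0.12, 0.24)
    n_areas: int = 7
    #: relative weight of species occupying k = 1, 2, ... areas
    occupancy: tuple[float, ...] = DEFAULT_OCCUPANCY
    localities_per_area: int = 2
    #: fraction of true species hidden behind another species' label
    cryptic_fraction: float = 0.033
    #: fraction of true species split across two labels
    oversplit_fraction: float = 0.015
    #: fraction of specimens left without a morphospecies label
    unassigned_fraction: float = 0.013
    #: fraction of multi-area species given per-area sub-ancestors
    geo_fraction: float = 0.1
    #: between-area divergence band for geographically structured species
    geo_divergence: tuple[float, float] = (0.02, 0.09)
    seed: int = 0

    def __post_init__(self) -> None:
        degenerate = self.intra_mean == self.inter_mean == 0.0
        if not degenerate and not 0 <= self.intra_mean < self.inter_mean:
            raise ValueError("infeasible divergence targets: need intra < inter")
        if self.inter_mean >= 0.7:
            raise ValueError("interspecific target too high to realize")
        for f in (
            self.cryptic_fraction,
            self.oversplit_fraction,
            self.unassigned_fraction,
            self.geo_fraction,
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth and error bookkeeping for a simulated dataset."""

    true_partition: Partition
    #: (species_a, species_b, shared_label) per injected cryptic merge
    merged_pairs: tuple[tuple[str, str, str], ...]
    #: (species, (label_a, label_b)) per injected oversplit
    oversplit_species: tuple[tuple[str, tuple[str, str]], ...]
    unassigned_ids: tuple[str, ...]
    #: realized areas per species
    occupancy: dict[str, tuple[str, ...]]
    config: GeneratorConfig

    @property
    def n_species(self) -> int:
        return self.true_partition.n_groups

    def expected_congruence(self) -> CongruenceReport:
        """Closed-form congruence of the true partition vs the labels.

        Each cryptic merge makes both involved true-species groups *split*
        (they cover only part of the shared label); each oversplit makes its
        group *lumped* (it covers two labels).  Everything else is perfect.
        """
        k = self.n_species
        n_merge = len(self.merged_pairs)
        n_over = len(self.oversplit_species)
        return CongruenceReport(
            n_species=k - n_merge + n_over,
            n_groups=k,
            n_perfect=k - 2 * n_merge - n_over,
            n_lumped=n_over,
            n_split=2 * n_merge,
            n_split_species=n_merge,
        )


def _mutate(seq: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute a Binomial(L, fraction) set of random sites."""
    n = rng.binomial(len(seq), min(max(fraction, 0.0), 1.0))
    if n == 0:
        return seq.copy()
    sites = rng.choice(len(seq), size=n, replace=False)
    out = seq.copy()
    out[sites] = (out[sites] + rng.integers(1, 4, size=n)) % 4
    return out


def _root_fraction(distance: float) -> float:
    """Per-species root divergence f giving pairwise distance d = 2f - 4/3 f^2.

    Two lineages independently substituting a fraction f of sites away from a
    common ancestor differ at a site if either changed it (and, when both
    did, the new bases differ with probability 2/3).
    """
    return 0.75 * (1.0 - math.sqrt(1.0 - (4.0 / 3.0) * distance))


def _draw_occupancy_k(
    occupancy: tuple[float, ...], n_areas: int, rng: np.random.Generator
) -> int:
    w = np.asarray(occupancy[:n_areas], dtype=float)
    w = w / w.sum()
    return int(rng.choice(len(w), p=w)) + 1


def simulate_sequences(
    config: GeneratorConfig,
) -> tuple[Alignment, SpecimenTable, SyntheticTruth]:
    """Simulate an aligned barcode dataset with specimen metadata and truth.

    Species ancestors radiate from a genus root with per-species divergences
    calibrated (net of tip-level variation) so that realized interspecific
    distances match the configured mean and band; specimens then mutate from
    their species (or per-area sub-)ancestor to realize the intraspecific
    target.  Morphospecies labels equal the true species except for injected
    cryptic merges, oversplits and unassignable specimens.
    """
    rng = np.random.default_rng(config.seed)
    length = config.seq_length
    root = rng.integers(0, 4, size=length)

    # Calibrate ancestor divergences net of the intraspecific contribution
    # that specimen-level mutations add to between-species tip distances.
    d_lo, d_hi = config.inter_range
    f_lo = _root_fraction(d_lo)
    f_hi = _root_fraction(max(d_hi - config.intra_mean, d_lo))
    f_target = _root_fraction(max(config.inter_mean - config.intra_mean, d_lo))
    pos = min(max((f_target - f_lo) / max(f_hi - f_lo, 1e-9), 0.05), 0.95)
    beta_a, beta_b = 4.0 * pos, 4.0 * (1.0 - pos)

    species = [f"sp{i + 1:03d}" for i in range(config.n_species)]
    area_names = [f"area{i + 1}" for i in range(config.n_areas)]

    ids: list[str] = []
    seqs: list[np.ndarray] = []
    true_assign: dict[str, str] = {}
    specimen_area: dict[str, str] = {}
    specimen_locality: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    occupancy: dict[str, tuple[str, ...]] = {}

    for si, sp in enumerate(species):
        f = f_lo + (f_hi - f_lo) * rng.beta(beta_a, beta_b)
        ancestor = _mutate(root, f, rng)
        g = min(rng.exponential(config.intra_mean / 2.0), 0.05)
        k = _draw_occupancy_k(config.occupancy, config.n_areas, rng)
        sp_areas = [
            area_names[a]
            for a in rng.choice(config.n_areas, size=k, replace=False)
        ]
        area_anc = {a: ancestor for a in sp_areas}
        if k > 1 and rng.random() < config.geo_fraction:
            delta = rng.uniform(*config.geo_divergence)
            area_anc = {a: _mutate(ancestor, delta / 2.0, rng) for a in sp_areas}
        n_spec = int(rng.choice(config.specimens_per_species))
        # Cover each occupied area at least once where specimen count allows.
        assigned_areas = [sp_areas[j % len(sp_areas)] for j in range(n_spec)]
        members[sp] = []
        for j, area in enumerate(assigned_areas):
            sid = f"{sp}-{j + 1:02d}"
            seq = _mutate(area_anc[area], g, rng)
            ids.append(sid)
            seqs.append(seq)
            true_assign[sid] = sp
            specimen_area[sid] = area
            specimen_locality[sid] = (
                f"{area}-L{rng.integers(1, config.localities_per_area + 1)}"
            )
            members[sp].append(sid)
        occupancy[sp] = tuple(sorted(set(assigned_areas)))

    # --- label-error injection -------------------------------------------
    labels: dict[str, str] = dict(true_assign)
    n_merge = round(config.cryptic_fraction * config.n_species)
    n_over = round(config.oversplit_fraction * config.n_species)
    pool = list(species)
    rng.shuffle(pool)
    merged: list[tuple[str, str, str]] = []
    for _ in range(n_merge):
        if len(pool) < 2:
            break
        a, b = pool.pop(), pool.pop()
        for sid in members[b]:
            labels[sid] = a
        merged.append((a, b, a))
    oversplit: list[tuple[str, tuple[str, str]]] = []
    for _ in range(n_over):
        sp = next((s for s in pool if len(members[s]) >= 2), None)
        if sp is None:
            break
        pool.remove(sp)
        # Split by area where the species spans several, else one specimen off.
        by_area: dict[str, list[str]] = {}
        for sid in members[sp]:
            by_area.setdefault(specimen_area[sid], []).append(sid)
        if len(by_area) >= 2:
            split_off = by_area[sorted(by_area)[-1]]
        else:
            split_off = [members[sp][-1]]
        alt = f"{sp}_b"
        for sid in split_off:
            labels[sid] = alt
        oversplit.append((sp, (sp, alt)))

    n_unassigned = round(config.unassigned_fraction * len(ids))
    unassigned: list[str] = []
    for sp in pool:
        if len(unassigned) >= n_unassigned:
            break
        if len(members[sp]) >= 3:
            unassigned.append(members[sp][0])
    unassigned_set = set(unassigned)

    alignment = Alignment.from_pairs(
        (sid, "".join(_BASES[s])) for sid, s in zip(ids, seqs)
    )
    table = SpecimenTable.from_records(
        (
            sid,
            None if sid in unassigned_set else labels[sid],
            specimen_area[sid],
            specimen_locality[sid],
        )
        for sid in ids
    )
    truth = SyntheticTruth(
        true_partition=Partition(true_assign, source="external"),
        merged_pairs=tuple(merged),
        oversplit_species=tuple(oversplit),
        unassigned_ids=tuple(unassigned),
        occupancy=occupancy,
        config=config,
    )
    return alignment, table, truth


# ---------------------------------------------------------------------------
# Chronogram simulation under the mixed Yule/coalescent generative process


def _coalescent_ages(n: int, scale: float, rng: np.random.Generator) -> list:
    """Kingman coalescent genealogy of n tips; returns nested node dicts."""
    nodes = [{"age": 0.0, "tip": j} for j in range(n)]
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(scale / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = nodes[max(i, j)], nodes[min(i, j)]
        nodes = [x for x in nodes if x is not a and x is not b]
        nodes.append({"age": t, "children": [a, b]})
    return nodes[0]


def _yule_species_tree(
    k_species: int, depth_scale: float, rng: np.random.Generator
):
    """Pure-birth species tree with k tips; returns (root_node, present)."""
    birth = 1.0 / depth_scale
    t = 0.0
    root = {"time": None}
    active = [root]
    while len(active) < k_species:
        t += rng.exponential(1.0 / (len(active) * birth))
        node = active[rng.integers(len(active))]
        left, right = {"time": None}, {"time": None}
        node["time"] = t
        node["children"] = [left, right]
        active.remove(node)
        active.extend([left, right])
    # Every species tip gets a stem of at least one depth-scale unit so that
    # speciation ages and within-species coalescence live on separated
    # timescales (their ratio is what the downstream delimitation exploits).
    present = t + depth_scale + rng.exponential(depth_scale / k_species)
    for i, node in enumerate(active):
        node["species"] = i
    return root, present


def _to_newick(node, parent_age: float) -> str:
    length = parent_age - node["age"]
    if "children" in node:
        inner = ",".join(_to_newick(c, node["age"]) for c in node["children"])
        return f"({inner}):{length:.12g}"
    return f"{node['label']}:{length:.12g}"


def simulate_gmyc_tree(
    k_species: int,
    tips_per_species: int | tuple[int, ...],
    species_depth_scale: float,
    coalescent_scale: float,
    seed: int,
    threshold_depth: float | None = None,
) -> tuple[UltrametricTree, Partition]:
    """Simulate an ultrametric tree under the mixed generative process.

    A pure-birth species tree (birth rate 1/``species_depth_scale``, every
    species tip carrying a stem of at least one depth-scale unit) has, below
    each tip, a neutral coalescent genealogy with per-pair timescale
    ``coalescent_scale``.  The generative process places all speciation
    events above a threshold depth and all within-species coalescence below
    it: genealogies are drawn conditioned on their root age staying under
    ``threshold_depth`` (default 4 x the coalescent scale, shallow enough to
    separate the two processes while leaving the coalescent essentially
    unconditioned) by rejection, with rescaling as a last resort.  The
    result is ultrametric by construction; returns the tree and the true
    species partition of its tips.
    """
    if not species_depth_scale > coalescent_scale > 0:
        raise ValueError("need species_depth_scale > coalescent_scale > 0")
    if k_species < 1:
        raise ValueError("need at least one species")
    if threshold_depth is None:
        threshold_depth = 4.0 * coalescent_scale
    rng = np.random.default_rng(seed)

    def n_tips_for(_: int) -> int:
        if isinstance(tips_per_species, int):
            return tips_per_species
        return int(rng.choice(tips_per_species))

    assignment: dict[str, str] = {}

    def attach_tips(node, species_idx: int, parent_age: float):
        sp = f"sp{species_idx + 1:03d}"
        n = n_tips_for(species_idx)
        if n == 1:
            node["age"] = 0.0
            node["label"] = f"{sp}_t1"
            assignment[node["label"]] = sp
            return
        cap = min(threshold_depth, 0.95 * parent_age)
        sub = None
        for _ in range(1000):
            cand = _coalescent_ages(n, coalescent_scale, rng)
            if cand["age"] < cap:
                sub = cand
                break
        if sub is None:
            sub = cand
            factor = 0.9 * cap / cand["age"]
            logger.warning(
                "coalescent depth exceeded species branch; rescaling by %.3g",
                factor,
            )
            _rescale(sub, factor)
        node.update(sub)
        node.pop("species", None)
        for j, tip in enumerate(_collect_tips(node)):
            tip["label"] = f"{sp}_t{j + 1}"
            assignment[tip["label"]] = sp

    def _rescale(node, factor):
        node["age"] *= factor
        for c in node.get("children", ()):
            _rescale(c, factor)

    def _collect_tips(node):
        if "children" not in node:
            return [node]
        out = []
        for c in node["children"]:
            out.extend(_collect_tips(c))
        return out

    if k_species == 1:
        n = n_tips_for(0)
        if n < 3:
            raise ValueError("single-species tree needs >= 3 tips")
        root = _coalescent_ages(n, coalescent_scale, rng)
        for j, tip in enumerate(_collect_tips(root)):
            tip["label"] = f"sp001_t{j + 1}"
            assignment[tip["label"]] = "sp001"
        newick = _to_newick(root, root["age"])
        newick = newick.rsplit(":", 1)[0] + ";"
        return read_newick_string(newick), Partition(assignment, "external")

    sroot, present = _yule_species_tree(k_species, species_depth_scale, rng)

    def convert(node, parent_age):
        age = 0.0 if node["time"] is None else present - node["time"]
        node["age"] = age
        if "children" in node:
            for c in node["children"]:
                convert(c, age)
        else:
            attach_tips(node, node["species"], parent_age)

    convert(sroot, present)
    newick = _to_newick(sroot, sroot["age"]).rsplit(":", 1)[0] + ";"
    return read_newick_string(newick), Partition(assignment, "external")


def simulate_community(
    n_areas: int,
    species_pool: int | list[str],
    occupancy_distribution: tuple[float, ...] = DEFAULT_OCCUPANCY,
    seed: int = 0,
) -> CommunityMatrix:
    """Assign each species to k areas drawn from the occupancy distribution."""
    rng = np.random.default_rng(seed)
    if isinstance(species_pool, int):
        species_pool = [f"sp{i + 1:03d}" for i in range(species_pool)]
    areas = [f"area{i + 1}" for i in range(n_areas)]
    occurrences = []
    for sp in species_pool:
        k = _draw_occupancy_k(tuple(occupancy_distribution), n_areas, rng)
        for a in rng.choice(n_areas, size=k, replace=False):
            occurrences.append((sp, areas[a]))
    return CommunityMatrix.from_occurrences(occurrences)
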