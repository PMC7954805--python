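"""Structured-coalescent simulation of unlinked biallelic SNPs.

Each SNP is an independent genealogy simulated backwards in time under a
continuous-time approximation of the Wright-Fisher coalescent: within a
deme holding k lineages and diploid effective size Ne, the next
coalescence is exponential with rate k(k-1)/(4 Ne) per generation.
Demographic events, processed in backward-time order, relocate lineages
between demes:

* a subsequent introduction wave at time t0w moves each UK lineage to the
  wave's origin deme independently with probability p_w (an admixture
  pulse seen backwards);
* the UK founding at t0a moves all remaining UK lineages to the first
  origin;
* native splits move child-deme lineages onto the parent lineage
  (t1: ALE->AKBC, t2: AKBC->COAST, t3: COAST->ancestral, t5: SOUTH->NORTH,
  t4: NORTH->ancestral).

One mutation per SNP is placed uniformly along the total branch length, so
every simulated site is polymorphic in the full sample.  Haploid genomes
are paired uniformly at random within demes into diploids (Hardy-Weinberg
pairing), and missing calls are injected i.i.d. at a configured rate to
mirror observed data.  The event loop is JIT-compiled with numba; a full
study-sized dataset (1435 SNPs x 798 haploids) simulates in well under a
second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .genotype_io import (
    MISSING,
    NATIVE_GROUPS,
    GenotypeMatrix,
    PopulationMap,
)
from .popgen_stats import StatCatalogue, build_scopes, summary_values
from .scenarios import PriorSpec, Scenario, ScenarioParams, draw_params

log = logging.getLogger(__name__)

__all__ = [
    "POP_INDEX",
    "SampleConfig",
    "CoalescentTree",
    "build_events",
    "simulate_tree",
    "drop_mutation",
    "simulate_snp_matrix",
    "panmictic_snps",
    "simulate_dataset",
    "reference_table",
]

#: Deme indices used by the simulation kernel.
POP_INDEX: dict[str, int] = {g: i for i, g in enumerate(NATIVE_GROUPS)}
POP_INDEX["UK"] = 5
POP_INDEX["ANC"] = 6
N_DEMES = 7

_TIME_GUARD = 1e9  # generations; non-convergence guard


@dataclass(frozen=True)
class SampleConfig:
    """Haploid sample counts per deme and the number of unlinked SNPs.

    Defaults mirror the study design: 1435 SNPs for 798 haploid genomes,
    twice the diploid group sizes ALE 45, AKBC 70, COAST 30, NORTH 62,
    SOUTH 42, UK 150.
    """

    haploids: dict[str, int] = field(
        default_factory=lambda: {
            "ALE": 90,
            "AKBC": 140,
            "COAST": 60,
            "NORTH": 124,
            "SOUTH": 84,
            "UK": 300,
        }
    )
    n_snps: int = 1435

    def __post_init__(self) -> None:
        for g, h in self.haploids.items():
            if g not in POP_INDEX or g == "ANC":
                raise ValueError(f"unknown deme {g!r}")
            if h < 0:
                raise ValueError(f"negative haploid count for {g}")
            if h % 2:
                raise ValueError(f"odd haploid count {h} for {g}; diploids required")
        if self.total_haploids < 2:
            raise ValueError("need at least 2 haploid samples in total")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")

    @property
    def groups(self) -> list[str]:
        """Sampled demes in canonical order."""
        order = list(NATIVE_GROUPS) + ["UK"]
        return [g for g in order if self.haploids.get(g, 0) > 0]

    @property
    def total_haploids(self) -> int:
        return sum(self.haploids.values())

    def tip_pops(self) -> np.ndarray:
        """Deme index per haploid tip, ordered by canonical deme blocks."""
        out = np.empty(self.total_haploids, dtype=np.int8)
        i = 0
        for g in self.groups:
            h = self.haploids[g]
            out[i : i + h] = POP_INDEX[g]
            i += h
        return out

    def diploid_samples(self) -> list[str]:
        names = []
        for g in self.groups:
            names += [f"{g}_{i:03d}" for i in range(self.haploids[g] // 2)]
        return names

    def popmap(self) -> PopulationMap:
        """Population map for the simulated diploids (population == group)."""
        return PopulationMap(
            {s: (s.rsplit("_", 1)[0], s.rsplit("_", 1)[0]) for s in self.diploid_samples()}
        )


# ---------------------------------------------------------------------------
# Event table construction

_SPLIT_MOVES = (
    ("t1", "ALE", "AKBC"),
    ("t2", "AKBC", "COAST"),
    ("t3", "COAST", "ANC"),
    ("t5", "SOUTH", "NORTH"),
    ("t4", "NORTH", "ANC"),
)


def build_events(scenario: Scenario, params: ScenarioParams):
    """Backward-time event arrays (time-sorted) for the simulation kernel.

    Returns (times, kinds, srcs, dsts, probs) where kind 0 moves every
    lineage of src to dst and kind 1 moves each src lineage independently
    with the given probability.
    """
    params.validate()
    rows = []
    for origin, t, p in zip(scenario.following, params.wave_times, params.wave_props):
        rows.append((t, 1, POP_INDEX["UK"], POP_INDEX[origin], p))
    rows.append((params.t0a, 0, POP_INDEX["UK"], POP_INDEX[scenario.first_origin], 1.0))
    for tname, child, parent in _SPLIT_MOVES:
        rows.append((params.splits[tname], 0, POP_INDEX[child], POP_INDEX[parent], 1.0))
    rows.sort(key=lambda r: r[0])
    times = np.array([r[0] for r in rows], dtype=np.float64)
    kinds = np.array([r[1] for r in rows], dtype=np.int8)
    srcs = np.array([r[2] for r in rows], dtype=np.int8)
    dsts = np.array([r[3] for r in rows], dtype=np.int8)
    probs = np.array([r[4] for r in rows], dtype=np.float64)
    return times, kinds, srcs, dsts, probs


def _ne_vector(params: ScenarioParams) -> np.ndarray:
    """4*Ne per deme index (the pairwise-coalescence rate denominator)."""
    ne4 = np.empty(N_DEMES, dtype=np.float64)
    for g, i in POP_INDEX.items():
        ne4[i] = 4.0 * params.ne[g]
    return ne4


_NO_EVENTS = (
    np.empty(0, np.float64),
    np.empty(0, np.int8),
    np.empty(0, np.int8),
    np.empty(0, np.int8),
    np.empty(0, np.float64),
)


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _coalesce_one(
    tip_pop, ne4, ev_time, ev_kind, ev_src, ev_dst, ev_p, parent, node_time, lin_node, lin_pop
):
    """Simulate one genealogy in place; returns node count or <0 on error."""
    n = tip_pop.size
    pop_count = np.zeros(7, np.int64)
    for i in range(n):
        lin_node[i] = i
        lin_pop[i] = tip_pop[i]
        node_time[i] = 0.0
        pop_count[tip_pop[i]] += 1
    k = n
    t = 0.0
    next_node = n
    ev_i = 0
    while k > 1:
        total_rate = 0.0
        for pp in range(7):
            c = pop_count[pp]
            if c > 1:
                total_rate += c * (c - 1) / ne4[pp]
        if ev_i < ev_time.size:
            t_ev = ev_time[ev_i]
        else:
            t_ev = 1e30
        if total_rate > 0.0:
            dt = np.random.exponential(1.0 / total_rate)
        else:
            dt = 1e30
        if t + dt < t_ev:
            t = t + dt
            if t > _TIME_GUARD:
                return -1
            u = np.random.random() * total_rate
            acc = 0.0
            chosen = -1
            for pp in range(7):
                c = pop_count[pp]
                if c > 1:
                    acc += c * (c - 1) / ne4[pp]
                    if u <= acc:
                        chosen = pp
                        break
            if chosen == -1:
                for pp in range(6, -1, -1):
                    if pop_count[pp] > 1:
                        chosen = pp
                        break
            c = pop_count[chosen]
            i1 = np.random.randint(0, c)
            i2 = np.random.randint(0, c - 1)
            if i2 >= i1:
                i2 += 1
            slot_a = -1
            slot_b = -1
            seen = 0
            for s in range(k):
                if lin_pop[s] == chosen:
                    if seen == i1:
                        slot_a = s
                    if seen == i2:
                        slot_b = s
                    seen += 1
                    if slot_a >= 0 and slot_b >= 0:
                        break
            parent[lin_node[slot_a]] = next_node
            parent[lin_node[slot_b]] = next_node
            node_time[next_node] = t
            lin_node[slot_a] = next_node
            lin_node[slot_b] = lin_node[k - 1]
            lin_pop[slot_b] = lin_pop[k - 1]
            k -= 1
            pop_count[chosen] -= 1
            next_node += 1
        else:
            if ev_i >= ev_time.size:
                return -2  # no coalescence possible and no events left
            t = t_ev
            kind = ev_kind[ev_i]
            src = ev_src[ev_i]
            dst = ev_dst[ev_i]
            p = ev_p[ev_i]
            for s in range(k):
                if lin_pop[s] == src:
                    if kind == 0 or np.random.random() < p:
                        lin_pop[s] = dst
                        pop_count[src] -= 1
                        pop_count[dst] += 1
            ev_i += 1
    return next_node


@njit(cache=True)
def _place_mutation(parent, node_time, n_nodes, below):
    """Uniform mutation on the non-root branches; marks the derived subtree."""
    total = 0.0
    for v in range(n_nodes - 1):
        total += node_time[parent[v]] - node_time[v]
    if total <= 0.0:
        return -1
    u = np.random.random() * total
    b = n_nodes - 2
    acc = 0.0
    for v in range(n_nodes - 1):
        acc += node_time[parent[v]] - node_time[v]
        if u <= acc:
            b = v
            break
    for v in range(n_nodes):
        below[v] = 0
    below[b] = 1
    # parents always carry a higher index than their children, so a single
    # descending sweep propagates subtree membership
    for v in range(n_nodes - 2, -1, -1):
        if v != b and below[parent[v]] == 1:
            below[v] = 1
    return b


@njit(cache=True)
def _sim_tree(seed, tip_pop, ne4, ev_time, ev_kind, ev_src, ev_dst, ev_p, parent, node_time):
    np.random.seed(seed)
    lin_node = np.zeros(tip_pop.size, np.int64)
    lin_pop = np.zeros(tip_pop.size, np.int8)
    return _coalesce_one(
        tip_pop, ne4, ev_time, ev_kind, ev_src, ev_dst, ev_p,
        parent, node_time, lin_node, lin_pop,
    )


@njit(cache=True)
def _sim_snps(seed, tip_pop, ne4, ev_time, ev_kind, ev_src, ev_dst, ev_p, n_snps):
    """Simulate n_snps polymorphic sites with polymorphism conditioning.

    A pool of n_snps genealogies is simulated; each SNP then draws its
    genealogy from the pool with probability proportional to total branch
    length and receives one uniformly placed mutation.  In the small-
    mutation-rate limit, conditioning a site on being segregating weights
    genealogies by total length exactly; resampling within the pool
    realises that weighting with O(1/pool) bias and negligible between-
    site dependence.
    """
    np.random.seed(seed)
    n = tip_pop.size
    nn = 2 * n - 1
    out = np.empty((n_snps, n), dtype=np.uint8)
    parents = np.empty((n_snps, nn), np.int64)
    times = np.empty((n_snps, nn), np.float64)
    lengths = np.empty(n_snps, np.float64)
    lin_node = np.zeros(n, np.int64)
    lin_pop = np.zeros(n, np.int8)
    below = np.zeros(nn, np.uint8)
    for j in range(n_snps):
        parents[j, nn - 1] = -1
        res = _coalesce_one(
            tip_pop, ne4, ev_time, ev_kind, ev_src, ev_dst, ev_p,
            parents[j], times[j], lin_node, lin_pop,
        )
        if res < 0:
            return out[:0]
        total = 0.0
        for v in range(nn - 1):
            total += times[j, parents[j, v]] - times[j, v]
        lengths[j] = total
        if total <= 0.0:
            return out[:0]
    cum = np.cumsum(lengths)
    tot = cum[-1]
    for s_i in range(n_snps):
        u = np.random.random() * tot
        j = np.searchsorted(cum, u)
        if j >= n_snps:
            j = n_snps - 1
        if _place_mutation(parents[j], times[j], nn, below) < 0:
            return out[:0]
        for i in range(n):
            out[s_i, i] = below[i]
    return out


# ---------------------------------------------------------------------------
# Python-level API


@dataclass
class CoalescentTree:
    """A realised genealogy: parent pointers, node times, tip demes.

    Tips occupy node indices 0..n-1 (time 0); internal nodes are numbered
    in coalescence order, so a parent's index always exceeds its child's.
    The root is the last node.
    """

    parent: np.ndarray
    node_time: np.ndarray
    tip_pop: np.ndarray

    @property
    def n_tips(self) -> int:
        return self.tip_pop.size

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.n_nodes - 1])

    @property
    def total_branch_length(self) -> float:
        v = np.arange(self.n_nodes - 1)
        return float((self.node_time[self.parent[v]] - self.node_time[v]).sum())

    def validate(self) -> None:
        n = self.n_tips
        if not np.all(self.node_time[:n] == 0.0):
            raise ValueError("tips must be at time 0 (ultrametric sample)")
        v = np.arange(self.n_nodes - 1)
        if not np.all(self.parent[v] > v):
            raise ValueError("parents must be created after their children")
        if np.any(self.node_time[self.parent[v]] < self.node_time[v]):
            raise ValueError("parent nodes must be older than their children")


def simulate_tree(
    scenario: Scenario | None,
    params: ScenarioParams | None,
    sample_config: SampleConfig,
    rng: np.random.Generator,
    *,
    panmictic_ne: float | None = None,
) -> CoalescentTree:
    """Simulate one genealogy under a scenario (or panmixia for checks).

    With ``panmictic_ne`` set, scenario/params may be None and all sampled
    lineages coalesce in a single deme of that size — the configuration
    used for closed-form validation (e.g. E[T_MRCA] = 2 Ne for n = 2).
    """
    tip_pop = sample_config.tip_pops()
    if panmictic_ne is not None:
        ne4 = np.full(N_DEMES, 4.0 * panmictic_ne)
        tip_pop = np.zeros_like(tip_pop)
        events = _NO_EVENTS
    else:
        if scenario is None or params is None:
            raise ValueError("scenario and params required unless panmictic_ne set")
        ne4 = _ne_vector(params)
        events = build_events(scenario, params)
    n = tip_pop.size
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1, dtype=np.float64)
    seed = int(rng.integers(1, 2**31 - 1))
    res = _sim_tree(seed, tip_pop, ne4, *events, parent, node_time)
    if res < 0:
        raise RuntimeError(
            "coalescent did not reach an MRCA within the time guard "
            f"({_TIME_GUARD:g} generations)"
        )
    return CoalescentTree(parent, node_time, tip_pop)


def drop_mutation(tree: CoalescentTree, rng: np.random.Generator) -> np.ndarray:
    """Place one mutation uniformly on the tree; returns tip 0/1 states.

    The mutation falls on a non-root branch, so the site is always
    polymorphic in the total sample.
    """
    nn = tree.n_nodes
    v = np.arange(nn - 1)
    lengths = tree.node_time[tree.parent[v]] - tree.node_time[v]
    total = float(lengths.sum())
    if total <= 0.0:
        raise ValueError("degenerate tree with zero total branch length")
    u = rng.random() * total
    b = int(np.searchsorted(np.cumsum(lengths), u))
    b = min(b, nn - 2)
    below = np.zeros(nn, dtype=np.uint8)
    below[b] = 1
    for node in range(nn - 2, -1, -1):
        if node != b and below[tree.parent[node]]:
            below[node] = 1
    return below[: tree.n_tips]


def simulate_snp_matrix(
    scenario: Scenario,
    params: ScenarioParams,
    sample_config: SampleConfig,
    seed: int,
) -> np.ndarray:
    """Haploid 0/1 matrix of shape (n_snps, total_haploids)."""
    tip_pop = sample_config.tip_pops()
    ne4 = _ne_vector(params)
    events = build_events(scenario, params)
    out = _sim_snps(int(seed), tip_pop, ne4, *events, sample_config.n_snps)
    if out.shape[0] != sample_config.n_snps:
        raise RuntimeError(
            f"simulation failed under scenario {scenario.id} "
            "(MRCA not reached within the time guard)"
        )
    return out


def panmictic_snps(n_haploids: int, ne: float, n_snps: int, seed: int) -> np.ndarray:
    """Haploid SNP matrix for a single panmictic deme (validation helper)."""
    tip_pop = np.zeros(n_haploids, dtype=np.int8)
    ne4 = np.full(N_DEMES, 4.0 * ne)
    out = _sim_snps(int(seed), tip_pop, ne4, *_NO_EVENTS, n_snps)
    if out.shape[0] != n_snps:
        raise RuntimeError("panmictic simulation failed")
    return out


def pair_haploids(
    hap: np.ndarray, sample_config: SampleConfig, rng: np.random.Generator
) -> np.ndarray:
    """Random within-deme pairing of haploids into diploid dosages.

    Returns an int8 array of shape (n_diploids, n_snps).
    """
    n_snps = hap.shape[0]
    blocks = []
    start = 0
    for g in sample_config.groups:
        h = sample_config.haploids[g]
        perm = start + rng.permutation(h)
        block = hap[:, perm[0::2]].astype(np.int8) + hap[:, perm[1::2]].astype(np.int8)
        blocks.append(block.T)
        start += h
    return np.concatenate(blocks, axis=0) if blocks else np.zeros((0, n_snps), np.int8)


def simulate_calls(
    scenario: Scenario,
    params: ScenarioParams,
    sample_config: SampleConfig,
    missing_profile: float | dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Diploid dosage array (n_diploids x n_snps) for one parameter draw.

    The container-free hot path behind :func:`simulate_dataset`, used when
    building reference tables.
    """
    seed = int(rng.integers(1, 2**31 - 1))
    hap = simulate_snp_matrix(scenario, params, sample_config, seed)
    calls = pair_haploids(hap, sample_config, rng)
    if isinstance(missing_profile, dict):
        rates = np.concatenate(
            [
                np.full(sample_config.haploids[g] // 2, missing_profile.get(g, 0.0))
                for g in sample_config.groups
            ]
        )[:, None]
    else:
        rates = float(missing_profile)
        if not 0.0 <= rates < 1.0:
            raise ValueError(f"missing rate must be in [0, 1), got {rates}")
    if np.any(np.asarray(rates) > 0):
        mask = rng.random(calls.shape) < rates
        calls[mask] = MISSING
    return calls


def simulate_dataset(
    scenario: Scenario,
    params: ScenarioParams,
    sample_config: SampleConfig,
    missing_profile: float | dict[str, float],
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Simulate a diploid genotype dataset under one parameter draw.

    ``missing_profile`` is either a global per-call missing rate or a
    per-deme rate dict; missing calls are injected i.i.d. per genotype.
    """
    calls = simulate_calls(scenario, params, sample_config, missing_profile, rng)
    samples = sample_config.diploid_samples()
    sites = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 1000 * (np.arange(sample_config.n_snps) + 1),
            "ref": "A",
            "alt": "T",
            "kind": "variant",
            "n_alt": 1,
        }
    )
    return GenotypeMatrix(samples, sites, calls)


def reference_table(
    scenario: Scenario,
    prior: PriorSpec,
    n_sims: int,
    sample_config: SampleConfig,
    seed: int,
    missing_profile: float | dict[str, float] = 0.0,
    catalogue: StatCatalogue | None = None,
    regional_groups: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Simulate a (parameters, summary statistics) table for one scenario.

    Row i is reproducible in isolation from ``(seed, i)``: each row owns a
    generator seeded with that pair.  Failed simulations (time-guard hits)
    are logged, resampled with a perturbed seed, and counted in the
    ``n_failed`` DataFrame attribute.
    """
    if catalogue is None:
        catalogue = StatCatalogue()
    popmap = sample_config.popmap()
    samples = sample_config.diploid_samples()
    scope_names, scope_idx, group_names, group_idx = build_scopes(
        samples, popmap, regional_groups
    )
    stat_names = catalogue.names(scope_names, group_names)
    rows = []
    n_failed = 0
    for i in range(n_sims):
        for attempt in range(20):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), i, attempt])
            )
            params = draw_params(scenario, prior, rng)
            try:
                gm_calls = simulate_calls(
                    scenario, params, sample_config, missing_profile, rng
                )
            except RuntimeError as exc:
                n_failed += 1
                log.warning("simulation %d attempt %d failed: %s", i, attempt, exc)
                continue
            stats = summary_values(gm_calls, scope_idx, group_idx, catalogue)
            row = {"model": scenario.id}
            row.update(params.flatten(scenario))
            row.update(zip(stat_names, stats))
            rows.append(row)
            break
        else:
            raise RuntimeError(f"simulation row {i} failed 20 times in a row")
    table = pd.DataFrame(rows)
    table.attrs["n_failed"] = n_failed
    table.attrs["stat_names"] = stat_names
    return table
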