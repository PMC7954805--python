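"""Demographic model space for the UK introduction history.

The native range is summarised by five genetic groups whose divergence
history is fixed (established from phylogenetic structure, not inferred
here): NORTH split from the ancestral population at t4 and SOUTH from the
NORTH lineage at t5; COAST split from the ancestral population at t3, the
Alaska-British Columbia group (AKBC) from the COAST lineage at t2, and the
Aleutian group (ALE) from the AKBC lineage at t1.  Candidate models differ
only in the introduction history of the UK deme: a founding introduction
from one native group at time t0a, optionally followed by admixture pulses
("waves") from further native groups at more recent times.

Model comparison is stepwise: round 1 compares the five single-origin
models; each later round k extends the best (k-1)-wave model by one new
origin, considering every choice of which origin came first, while earlier
rounds' best models are carried into the comparison.  With the previous
best origin set S (|S| = k-1) drawn from 5 groups this yields (6-k)*k new
k-wave models: 5, 8, 9, 8, 5 for k = 1..5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genotype_io import NATIVE_GROUPS

__all__ = [
    "NATIVE_GROUPS",
    "Scenario",
    "ScenarioParams",
    "PriorSpec",
    "SPLIT_PARENT",
    "enumerate_round",
    "round_candidates",
    "draw_params",
]

#: Backward-in-time lineage movements of the native topology:
#: child group -> (parent deme, split-time parameter name).
SPLIT_PARENT: dict[str, tuple[str, str]] = {
    "ALE": ("AKBC", "t1"),
    "AKBC": ("COAST", "t2"),
    "COAST": ("ANC", "t3"),
    "SOUTH": ("NORTH", "t5"),
    "NORTH": ("ANC", "t4"),
}


@dataclass(frozen=True)
class Scenario:
    """One introduction history: a first origin plus later wave origins.

    ``following`` is semantically an unordered set; the stored tuple order
    is the enumeration/display order.
    """

    id: str
    first_origin: str
    following: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        origins = (self.first_origin,) + self.following
        if len(set(origins)) != len(origins):
            raise ValueError(f"duplicate origins in scenario {self.id}: {origins}")
        for g in origins:
            if g not in NATIVE_GROUPS:
                raise ValueError(f"unknown native group {g!r} in scenario {self.id}")
        if not 1 <= len(origins) <= 5:
            raise ValueError(f"scenario {self.id} must have 1..5 waves")

    @property
    def n_waves(self) -> int:
        return 1 + len(self.following)

    @property
    def origins(self) -> frozenset[str]:
        return frozenset((self.first_origin,) + self.following)

    def describe(self) -> str:
        tail = ",".join(self.following) if self.following else "-"
        return f"{self.id}: first={self.first_origin} following={tail}"


def _canonical(groups) -> list[str]:
    return [g for g in NATIVE_GROUPS if g in groups]


def enumerate_round(previous_best: Scenario | None, round_k: int) -> list[Scenario]:
    """New k-wave scenarios for one comparison round.

    Round 1 is one single-origin model per native group.  For k > 1 the
    previous round's best (k-1)-wave model contributes its origin set S;
    for every new group X not in S the candidate origin set is S + {X},
    and one scenario is created per choice of first origin among its k
    members.  Identifiers are letter-of-round plus a sequence number, in
    the order: previous members as first origin (each crossed with the new
    groups in canonical order), then each new group itself as first origin.
    """
    if not 1 <= round_k <= 5:
        raise ValueError(f"round_k must be in 1..5, got {round_k}")
    letter = chr(ord("A") + round_k - 1)
    if round_k == 1:
        if previous_best is not None:
            raise ValueError("round 1 takes no previous best scenario")
        return [Scenario(f"{letter}{i+1}", g) for i, g in enumerate(NATIVE_GROUPS)]

    if previous_best is None:
        raise ValueError(f"round {round_k} requires the best {round_k-1}-wave model")
    if previous_best.n_waves != round_k - 1:
        raise ValueError(
            f"previous best {previous_best.id} has {previous_best.n_waves} waves; "
            f"round {round_k} needs a {round_k-1}-wave model"
        )

    members = (previous_best.first_origin,) + previous_best.following
    new_groups = [g for g in NATIVE_GROUPS if g not in members]
    out: list[Scenario] = []
    num = 1
    if round_k == 5:
        # All-origins round: one scenario per choice of first origin.  The
        # stepwise-table numbering convention places the newly added origin
        # before the last carried origin.
        firsts = list(members[:-1]) + new_groups + [members[-1]]
        for first in firsts:
            rest = tuple(m for m in members if m != first)
            rest = rest if first in members else members
            out.append(Scenario(f"{letter}{num}", first, rest + tuple(
                x for x in new_groups if x != first and x not in rest
            )))
            num += 1
        return out
    for first in members:
        rest = tuple(m for m in members if m != first)
        for x in new_groups:
            out.append(Scenario(f"{letter}{num}", first, rest + (x,)))
            num += 1
    for x in new_groups:
        out.append(Scenario(f"{letter}{num}", x, members))
        num += 1
    return out


def round_candidates(
    history: list[Scenario], new_scenarios: list[Scenario]
) -> list[Scenario]:
    """Candidate list for a round: earlier rounds' best models + new ones."""
    for i, s in enumerate(history):
        if s.n_waves != i + 1:
            raise ValueError("history must be ordered by wave count (1, 2, ...)")
    candidates = list(history) + list(new_scenarios)
    ids = [s.id for s in candidates]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate scenario ids: {dup}")
    return candidates


# ---------------------------------------------------------------------------
# Parameters and priors


@dataclass(frozen=True)
class ScenarioParams:
    """One draw of all demographic parameters for a scenario.

    Effective sizes are diploid; all times are in generations before
    present.  ``wave_times``/``wave_props`` align with the scenario's
    ``following`` tuple (empty for single-introduction models).
    """

    ne: dict[str, float]  # ALE, AKBC, COAST, NORTH, SOUTH, UK, ANC
    t0a: float
    wave_times: tuple[float, ...]
    wave_props: tuple[float, ...]
    splits: dict[str, float]  # t1..t5

    def validate(self) -> None:
        required = set(NATIVE_GROUPS) | {"UK", "ANC"}
        if set(self.ne) != required:
            raise ValueError(f"ne must cover {sorted(required)}")
        if any(v <= 0 for v in self.ne.values()):
            raise ValueError("effective sizes must be positive")
        if set(self.splits) != {"t1", "t2", "t3", "t4", "t5"}:
            raise ValueError("splits must define t1..t5")
        s = self.splits
        if not (s["t1"] < s["t2"] < s["t3"]):
            raise ValueError("require t1 < t2 < t3")
        if not (s["t5"] < s["t4"]):
            raise ValueError("require t5 < t4")
        if any(v <= 0 for v in s.values()):
            raise ValueError("split times must be positive")
        if not self.t0a < min(s.values()):
            raise ValueError("UK founding t0a must predate no native split")
        if len(self.wave_times) != len(self.wave_props):
            raise ValueError("wave_times and wave_props length mismatch")
        for t in self.wave_times:
            if not 0 < t < self.t0a:
                raise ValueError("wave times must fall in (0, t0a)")
        for p in self.wave_props:
            if not 0.001 <= p <= 0.999:
                raise ValueError("wave proportions must lie in [0.001, 0.999]")

    def flatten(self, scenario: Scenario) -> dict[str, float]:
        """Parameter row for reference tables, keyed with a par_ prefix."""
        row = {f"par_ne_{k}": v for k, v in self.ne.items()}
        row["par_t0a"] = self.t0a
        row.update({f"par_{k}": v for k, v in self.splits.items()})
        for origin, t, p in zip(scenario.following, self.wave_times, self.wave_props):
            row[f"par_twave_{origin}"] = t
            row[f"par_pwave_{origin}"] = p
        return row


@dataclass(frozen=True)
class Dist:
    """A 1-D prior distribution: uniform or log-uniform over (low, high)."""

    family: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "loguniform"):
            raise ValueError(f"unknown family {self.family!r}")
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise ValueError("bounds must be finite")
        if not self.low < self.high:
            raise ValueError(f"need low < high, got ({self.low}, {self.high})")
        if self.family == "loguniform" and self.low <= 0:
            raise ValueError("loguniform requires positive bounds")

    def draw(self, rng: np.random.Generator, size=None):
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, size)
        return np.exp(rng.uniform(np.log(self.low), np.log(self.high), size))


@dataclass(frozen=True)
class PriorSpec:
    """Prior distributions for every demographic parameter.

    Defaults: log-uniform effective sizes over [1e2, 1e5]; UK founding
    time uniform over [10, 500] generations; subsequent wave times uniform
    over [5, t0a] (conditioned on the drawn t0a); native split times
    uniform over [500, 20000] with the topology orderings imposed by
    sorting; wave migrant proportions uniform over [0.001, 0.999].
    """

    ne: Dist = Dist("loguniform", 1e2, 1e5)
    ne_overrides: dict[str, Dist] = field(default_factory=dict)
    t0a: Dist = Dist("uniform", 10.0, 500.0)
    wave_time_min: float = 5.0
    split: Dist = Dist("uniform", 500.0, 20000.0)
    wave_prop: Dist = Dist("uniform", 0.001, 0.999)

    def ne_dist(self, pop: str) -> Dist:
        return self.ne_overrides.get(pop, self.ne)


MAX_REJECTIONS = 1000


def draw_params(
    scenario: Scenario, prior: PriorSpec, rng: np.random.Generator
) -> ScenarioParams:
    """Sample one parameter set satisfying all ordering constraints.

    Split-time orderings are imposed by sorting independent draws; the
    t0a-below-all-splits constraint is enforced by rejection resampling.
    """
    for _ in range(MAX_REJECTIONS):
        ne = {p: float(prior.ne_dist(p).draw(rng)) for p in NATIVE_GROUPS}
        ne["UK"] = float(prior.ne_dist("UK").draw(rng))
        ne["ANC"] = float(prior.ne_dist("ANC").draw(rng))
        t0a = float(prior.t0a.draw(rng))
        t1, t2, t3 = np.sort(prior.split.draw(rng, 3))
        t5, t4 = np.sort(prior.split.draw(rng, 2))
        splits = {
            "t1": float(t1),
            "t2": float(t2),
            "t3": float(t3),
            "t4": float(t4),
            "t5": float(t5),
        }
        if t0a >= min(splits.values()):
            continue
        n_follow = len(scenario.following)
        if prior.wave_time_min >= t0a:
            continue
        wave_times = tuple(
            float(x) for x in rng.uniform(prior.wave_time_min, t0a, n_follow)
        )
        wave_props = tuple(float(x) for x in prior.wave_prop.draw(rng, n_follow))
        params = ScenarioParams(ne, t0a, wave_times, wave_props, splits)
        try:
            params.validate()
        except ValueError:
            continue
        return params
    raise ValueError(
        "could not satisfy parameter ordering constraints after "
        f"{MAX_REJECTIONS} draws; check that the t0a prior "
        f"({prior.t0a.low}, {prior.t0a.high}) lies below the split prior "
        f"({prior.split.low}, {prior.split.high})"
    )


def tighten_prior(prior: PriorSpec, **dists: Dist) -> PriorSpec:
    """Return a copy of a prior with some fields replaced (config helper)."""
    return replace(prior, **dists)
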