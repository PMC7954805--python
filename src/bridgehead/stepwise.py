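"""Stepwise model search: enumerate, simulate, classify, promote.

Round k compares the previous rounds' best models (carried over) against
the new k-wave scenarios built around the best (k-1)-wave origin set.
Votes come from a classification forest trained on per-scenario reference
tables; tables are cached by scenario id so carried-over models are never
re-simulated.  The model promoted to seed round k+1 is the top-voted
*k-wave* model of the round — a simpler carried-over model may well
out-vote it, and both facts are recorded.  The final best model is the
overall vote argmax of the last round.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abcrf_engine import ModelChoiceResult, classify, train_classifier
from .coalsim import SampleConfig, reference_table
from .popgen_stats import StatCatalogue, SummaryStatVector
from .scenarios import PriorSpec, Scenario, enumerate_round, round_candidates

log = logging.getLogger(__name__)

__all__ = ["RoundRecord", "SearchResult", "run_search", "export_table1", "export_confusion"]


@dataclass
class RoundRecord:
    """Everything recorded for one comparison round."""

    round_k: int
    candidates: list[Scenario]
    result: ModelChoiceResult
    promoted: Scenario  # top-voted k-wave model, seeds the next round
    overall_best: str  # vote argmax across all candidates of the round


@dataclass
class SearchResult:
    """Per-round records, the promotion path, and the final best scenario."""

    rounds: list[RoundRecord]
    best_path: list[Scenario]
    final_best: Scenario
    seed: int
    sims_per_model: int
    n_trees: int
    early_stop_reason: str | None = None
    scenario_index: dict[str, Scenario] = field(default_factory=dict)


def _scenario_seed(master_seed: int, scenario_id: str) -> int:
    """Stable per-scenario simulation seed below 2**31."""
    return (int(master_seed) * 100003 + zlib.crc32(scenario_id.encode())) % (2**31 - 1)


def run_search(
    observed: SummaryStatVector,
    prior: PriorSpec,
    sample_config: SampleConfig,
    sims_per_model: int = 1000,
    max_waves: int = 5,
    n_trees: int = 500,
    seed: int = 0,
    missing_profile: float | dict[str, float] = 0.0,
    catalogue: StatCatalogue | None = None,
    regional_groups: dict[str, tuple[str, ...]] | None = None,
    carried_supermajority: float | None = None,
    cache: dict | None = None,
    with_posterior: bool = True,
) -> SearchResult:
    """Run the iterative model comparison up to ``max_waves`` rounds.

    ``carried_supermajority`` optionally stops early when a carried-over
    simpler model takes at least that fraction of the round's votes
    (disabled by default, matching a full run to five waves).

    ``cache`` is an optional dict memoizing reference tables and trained
    forests across calls.  Both are deterministic functions of the seed
    and settings, so sharing a cache between calls with identical seed,
    budgets and priors changes nothing but the runtime (e.g. when
    classifying many observed datasets against the same model space).
    """
    if sims_per_model < 50:
        raise ValueError("need at least 50 simulations per model")
    if not 1 <= max_waves <= 5:
        raise ValueError("max_waves must be in 1..5")
    if cache is None:
        cache = {}
    tables: dict[str, pd.DataFrame] = cache.setdefault("tables", {})
    forests: dict[tuple, object] = cache.setdefault("forests", {})
    best_path: list[Scenario] = []
    rounds: list[RoundRecord] = []
    index: dict[str, Scenario] = {}
    early_stop = None
    for k in range(1, max_waves + 1):
        new = enumerate_round(best_path[-1] if best_path else None, k)
        candidates = round_candidates(best_path, new)
        for sc in candidates:
            index[sc.id] = sc
            if sc.id not in tables:
                log.info(
                    "round %d: simulating %d datasets under %s",
                    k, sims_per_model, sc.id,
                )
                tables[sc.id] = reference_table(
                    sc,
                    prior,
                    sims_per_model,
                    sample_config,
                    _scenario_seed(seed, sc.id),
                    missing_profile=missing_profile,
                    catalogue=catalogue,
                    regional_groups=regional_groups,
                )
        forest_key = (tuple(sorted(sc.id for sc in candidates)), seed + k)
        if forest_key in forests:
            forest = forests[forest_key]
        else:
            train = pd.concat(
                [tables[sc.id] for sc in candidates], ignore_index=True
            )
            forest = train_classifier(train, n_trees=n_trees, seed=seed + k)
            forests[forest_key] = forest
        result = classify(forest, observed, with_posterior=with_posterior)
        new_ids = {sc.id for sc in new}
        promoted_id = max(
            sorted(new_ids), key=lambda m: result.votes.get(m, 0)
        )
        promoted = index[promoted_id]
        rounds.append(
            RoundRecord(
                round_k=k,
                candidates=candidates,
                result=result,
                promoted=promoted,
                overall_best=result.selected_model,
            )
        )
        best_path.append(promoted)
        log.info(
            "round %d: promoted %s (%d votes); overall best %s",
            k, promoted.id, result.votes[promoted.id], result.selected_model,
        )
        if (
            carried_supermajority is not None
            and result.selected_model not in new_ids
            and result.votes[result.selected_model] >= carried_supermajority * n_trees
        ):
            early_stop = (
                f"carried-over model {result.selected_model} holds a "
                f"supermajority of votes in round {k}"
            )
            break
    final_best = index[rounds[-1].overall_best]
    return SearchResult(
        rounds=rounds,
        best_path=best_path,
        final_best=final_best,
        seed=seed,
        sims_per_model=sims_per_model,
        n_trees=n_trees,
        early_stop_reason=early_stop,
        scenario_index=index,
    )


def export_table1(result: SearchResult) -> pd.DataFrame:
    """Flat per-round candidate table: group, origins, votes, selection.

    One row per candidate per round, with the vote count, the posterior
    probability on the round's selected model, and a ``selected`` flag.
    """
    rows = []
    for rec in result.rounds:
        letter = chr(ord("A") + rec.round_k - 1)
        for sc in rec.candidates:
            selected = sc.id == rec.overall_best
            rows.append(
                {
                    "model_group": letter,
                    "n_origins": sc.n_waves,
                    "model": sc.id,
                    "first_origin": sc.first_origin,
                    "following_origins": ",".join(sc.following) or "-",
                    "votes": rec.result.votes[sc.id],
                    "posterior_probability": (
                        rec.result.posterior_probability if selected else np.nan
                    ),
                    "selected": selected,
                    "promoted": sc.id == rec.promoted.id,
                }
            )
    return pd.DataFrame(rows)


def export_confusion(result: ModelChoiceResult) -> pd.DataFrame:
    """Confusion matrix with per-model classification error and precision.

    Rows are simulated (true) models, columns classified models, plus
    ``classification_error`` (1 - recall) and ``precision`` columns.
    """
    out = result.oob_confusion.copy()
    out["classification_error"] = result.per_model_error
    out["precision"] = result.per_model_precision
    return out
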