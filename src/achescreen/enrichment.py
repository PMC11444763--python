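"""Multi-round similarity-search enrichment campaigns.

The screening loop alternates similarity search and affinity prediction:
round 0 scores the initial library; each later round takes the strongest
predicted binders of the previous round as seeds, finds their fingerprint
neighbors in the search library, predicts their affinity, and summarizes the
predicted-dG distribution (median and interquartile range).  A successful
campaign shifts the round distributions toward more negative dG — the
enrichment the procedure is designed to produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .affinity_model import AffinityModel, predict, select_top
from .chem_library import CompoundRecord, Library, neighbor_search

__all__ = [
    "RoundSummary",
    "CampaignConfig",
    "summarize_distribution",
    "run_round",
    "run_campaign",
]


@dataclass(frozen=True)
class RoundSummary:
    """Distribution summary of predicted dG over one round's compound set."""

    round_index: int
    n_unique: int
    median: float
    q1: float
    q3: float
    best_id: str
    best_dg: float

    def __post_init__(self) -> None:
        if self.n_unique < 1:
            raise ValueError("a round summary needs at least one compound")
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles out of order")

    def to_dict(self) -> dict:
        return {
            "round_index": self.round_index,
            "n_unique": self.n_unique,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "best_id": self.best_id,
            "best_dg": self.best_dg,
        }


@dataclass(frozen=True)
class CampaignConfig:
    """Campaign shape: round count, similarity cutoff, per-round seed selection.

    ``selections[r]`` (a ``(mode, value)`` pair for :func:`select_top`) picks
    the seeds for similarity round ``r+1`` from round ``r``'s output, so the
    list has one entry per similarity round.
    """

    n_rounds: int
    sim_cutoff: float = 0.9
    selections: Sequence[tuple[str, float]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if not 0.0 <= self.sim_cutoff <= 1.0:
            raise ValueError("sim_cutoff must be in [0, 1]")
        if len(self.selections) != self.n_rounds:
            raise ValueError(
                f"need one selection per round: {len(self.selections)} given "
                f"for {self.n_rounds} rounds"
            )


def summarize_distribution(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation of order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty distribution")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def _summary(round_index: int, records: Sequence[CompoundRecord]) -> RoundSummary:
    dgs = np.array([r.dg_pred for r in records], dtype=float)
    med, q1, q3 = summarize_distribution(dgs)
    best = min(records, key=lambda r: (r.dg_pred, r.id))
    return RoundSummary(
        round_index=round_index,
        n_unique=len(records),
        median=med,
        q1=q1,
        q3=q3,
        best_id=best.id,
        best_dg=float(best.dg_pred),
    )


def run_round(
    library: Library,
    seeds: Sequence[CompoundRecord],
    sim_cutoff: float,
    model: AffinityModel,
    round_index: int = 1,
) -> tuple[list[CompoundRecord], RoundSummary]:
    """One similarity round: search, predict, summarize the new hits.

    Seeds are excluded from the hit set, so the summary describes newly
    identified compounds only.
    """
    hits = neighbor_search(library, seeds, sim_cutoff)
    if not hits:
        raise ValueError(
            f"similarity round {round_index} found no hits "
            f"(cutoff {sim_cutoff} may be too high for this library)"
        )
    scored = predict(model, Library(hits))
    hit_records = [
        CompoundRecord(
            id=r.id,
            smiles=r.smiles,
            features=r.features,
            fingerprint=r.fingerprint,
            dg_pred=r.dg_pred,
            dg_exp=r.dg_exp,
            activity=r.activity,
            source_round=round_index,
        )
        for r in scored.records
    ]
    return hit_records, _summary(round_index, hit_records)


def run_campaign(
    library: Library,
    initial_library: Library,
    config: CampaignConfig,
    model: AffinityModel,
) -> tuple[list[RoundSummary], list[CompoundRecord]]:
    """Run the full enrichment loop.

    Round 0 predicts over ``initial_library`` and summarizes it; for each
    similarity round r = 1..n_rounds, seeds are chosen by
    ``config.selections[r-1]`` from the previous round's compound set and
    their neighbors in ``library`` are scored.  Rounds are summarized
    independently (hit sets are not merged across rounds).  Returns every
    round summary plus the final round's hits ranked ascending by predicted
    dG.
    """
    scored_initial = predict(model, initial_library)
    current: list[CompoundRecord] = list(scored_initial.records)
    summaries = [_summary(0, current)]
    for r in range(1, config.n_rounds + 1):
        mode, value = config.selections[r - 1]
        seeds = select_top(current, mode, value)
        if not seeds:
            raise ValueError(
                f"selection {mode}:{value} after round {r - 1} produced no seeds"
            )
        current, summary = run_round(
            library, seeds, config.sim_cutoff, model, round_index=r
        )
        summaries.append(summary)
    final_hits = sorted(current, key=lambda rec: (rec.dg_pred, rec.id))
    return summaries, final_hits
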