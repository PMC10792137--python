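"""Modified-Delphi computations behind the METRICS weights.

Three pieces of the expert-panel procedure are implemented:

1. **Consensus per voting round.** Panelists rate each candidate item on a
   five-point Likert scale. "Strongly agree" + "agree" form the agreement
   rate; "strongly disagree" + "disagree" the disagreement rate; neutral
   votes count toward neither side. Consensus requires either rate to reach
   the a-priori threshold of 75% (compared with >=). An item with no
   consensus is re-voted once; failing again, it is removed, and consensus
   disagreement removes an item immediately.

2. **Rank-sum weighting.** Panelists rank the 9 categories, and the items
   within each category, by importance. Ranks are aggregated per entity as
   the median over panelists (an even panel can yield half-integer
   medians). Median ranks convert to importance scores by

       score = (N + 1) - median_rank

   where N is the number of entities at that level, and the scores are
   rescaled to sum to 1, giving the level's weights. The final weight of an
   item is the product of its category's weight and its within-category
   weight; the 30 final weights again sum to 1.

3. **Certification.** :func:`invert_weights_to_ranks` brute-force searches
   half-integer median-rank configurations whose derived final weights
   match a published 4-decimal weight table, certifying that the packaged
   instrument is reproducible by the derivation chain end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Iterable, Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    CertificationError,
    DomainError,
    FlowError,
    SchemaError,
)
from .instrument import Instrument

__all__ = [
    "Vote",
    "VoteTable",
    "ConsensusResult",
    "RankMatrix",
    "WeightDerivation",
    "FinalWeights",
    "consensus_status",
    "apply_round_flow",
    "aggregate_median_ranks",
    "rank_to_scores",
    "derive_weight_table",
    "invert_weights_to_ranks",
    "round_weight",
]

Vote = Literal[
    "strongly_agree", "agree", "neutral", "disagree", "strongly_disagree"
]
VOTE_LABELS: tuple[str, ...] = (
    "strongly_agree",
    "agree",
    "neutral",
    "disagree",
    "strongly_disagree",
)
_AGREE_SIDE = frozenset({"strongly_agree", "agree"})
_DISAGREE_SIDE = frozenset({"strongly_disagree", "disagree"})

ConsensusStatus = Literal["consensus_agree", "consensus_disagree", "no_consensus"]
Disposition = Literal[
    "retained", "removed_no_consensus", "removed_disagreement", "pending"
]


class VoteTable:
    """Likert-5 votes, one row per (panelist, item).

    Wraps a DataFrame with columns ``panelist_id, item_key, vote``. Vote
    labels are case-insensitive on input and normalized to the snake_case
    forms in :data:`VOTE_LABELS`. At most one vote per (panelist, item).
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"panelist_id", "item_key", "vote"}
        if not required.issubset(frame.columns):
            raise SchemaError(
                f"vote table needs columns {sorted(required)}, "
                f"got {list(frame.columns)}"
            )
        frame = frame.copy()
        frame["vote"] = (
            frame["vote"].astype(str).str.strip().str.lower().str.replace(" ", "_")
        )
        bad = frame.loc[~frame["vote"].isin(VOTE_LABELS), "vote"].unique()
        if len(bad):
            raise SchemaError(f"unknown vote labels: {sorted(bad)}")
        dup = frame.duplicated(subset=["panelist_id", "item_key"])
        if dup.any():
            pairs = frame.loc[dup, ["panelist_id", "item_key"]].values.tolist()
            raise SchemaError(f"duplicate votes for (panelist, item): {pairs}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "VoteTable":
        return cls(pd.read_csv(path, dtype=str))

    def item_keys(self) -> list[str]:
        return list(self.frame["item_key"].unique())

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class ConsensusResult:
    item_key: str
    n_votes: int
    agreement_rate: float
    disagreement_rate: float
    status: ConsensusStatus


def consensus_status(
    votes: VoteTable,
    item_key: str,
    threshold: float = 0.75,
    include_neutral_in_denominator: bool = True,
) -> ConsensusResult:
    """Consensus outcome for one item from one round's votes.

    Agreement rate = (#strongly_agree + #agree) / n; disagreement likewise
    for the disagree side; neutral votes enter neither numerator. By
    default n counts every submitted vote including neutrals (the strict
    reading of "neutral counts toward neither decision");
    ``include_neutral_in_denominator=False`` drops neutrals from n as well.
    Consensus is declared when either rate reaches ``threshold`` (>=).
    """
    if not 0.0 < threshold <= 1.0:
        raise DomainError(f"threshold must be in (0, 1], got {threshold}")
    sub = votes.frame[votes.frame["item_key"] == item_key]
    if sub.empty:
        raise SchemaError(f"no votes recorded for item {item_key!r}")
    n_agree = int(sub["vote"].isin(_AGREE_SIDE).sum())
    n_disagree = int(sub["vote"].isin(_DISAGREE_SIDE).sum())
    n = len(sub) if include_neutral_in_denominator else n_agree + n_disagree
    if n == 0:
        raise SchemaError(
            f"item {item_key!r}: all votes neutral and neutrals excluded "
            "from the denominator"
        )
    agreement = n_agree / n
    disagreement = n_disagree / n
    if agreement >= threshold:
        status: ConsensusStatus = "consensus_agree"
    elif disagreement >= threshold:
        status = "consensus_disagree"
    else:
        status = "no_consensus"
    return ConsensusResult(
        item_key=item_key,
        n_votes=len(sub),
        agreement_rate=agreement,
        disagreement_rate=disagreement,
        status=status,
    )


def apply_round_flow(
    previous: Mapping[str, ConsensusResult],
    current: Mapping[str, ConsensusResult],
) -> dict[str, Disposition]:
    """Combine two consecutive voting rounds into item dispositions.

    Rules: consensus agreement at either round retains the item; consensus
    disagreement at any round removes it without further discussion; no
    consensus in the first round sends the item to the second, and a second
    no-consensus removes it. The current round must re-vote exactly the
    unresolved items of the previous round; newly proposed items (absent
    from ``previous``) may also appear, and one that again reaches no
    consensus is ``pending`` (it gets its own second vote later).

    Raises :class:`FlowError` if the current round re-votes an item already
    resolved previously, or omits an unresolved one.
    """
    dispositions: dict[str, Disposition] = {}
    unresolved = {
        k for k, r in previous.items() if r.status == "no_consensus"
    }
    for key, result in previous.items():
        if result.status == "consensus_agree":
            dispositions[key] = "retained"
        elif result.status == "consensus_disagree":
            dispositions[key] = "removed_disagreement"

    resolved_revoted = (set(current) & set(previous)) - unresolved
    if resolved_revoted:
        raise FlowError(
            f"items re-voted although already resolved: {sorted(resolved_revoted)}"
        )
    missing = unresolved - set(current)
    if missing:
        raise FlowError(
            f"unresolved items missing from the next round: {sorted(missing)}"
        )

    for key, result in current.items():
        is_revote = key in unresolved
        if result.status == "consensus_agree":
            dispositions[key] = "retained"
        elif result.status == "consensus_disagree":
            dispositions[key] = "removed_disagreement"
        else:
            dispositions[key] = "removed_no_consensus" if is_revote else "pending"
    return dispositions


class RankMatrix:
    """Panelist-by-entity importance ranks at one hierarchy level.

    ``level`` is ``"category"`` or ``"item"``; for the item level,
    ``group_key`` names the parent category. ``ranks`` is a DataFrame
    (index panelist_id, one column per entity) where every row is a
    permutation of 1..N — each panelist produces a strict ranking, ties
    arise only in the aggregated medians. Panelists with missing entries
    are dropped listwise on construction; a complete but non-permutation
    row is rejected with the panelist named.
    """

    def __init__(
        self,
        ranks: pd.DataFrame,
        level: Literal["category", "item"] = "category",
        group_key: str = "",
    ) -> None:
        if ranks.shape[1] == 0 or ranks.shape[0] == 0:
            raise SchemaError("rank matrix must have at least one panelist and entity")
        ranks = ranks.dropna(axis=0, how="any")
        if ranks.shape[0] == 0:
            raise SchemaError("no panelist submitted a complete ranking")
        ranks = ranks.astype(int)
        n = ranks.shape[1]
        expected = set(range(1, n + 1))
        for panelist, row in ranks.iterrows():
            if set(row) != expected:
                raise SchemaError(
                    f"panelist {panelist!r}: ranks {sorted(row)} are not a "
                    f"permutation of 1..{n}"
                )
        self.ranks = ranks
        self.level = level
        self.group_key = group_key

    @property
    def n_entities(self) -> int:
        return self.ranks.shape[1]

    @property
    def n_panelists(self) -> int:
        return self.ranks.shape[0]

    @property
    def entities(self) -> list:
        return list(self.ranks.columns)

    @classmethod
    def from_long(
        cls,
        frame: pd.DataFrame,
        level: Literal["category", "item"] = "category",
        group_key: str = "",
    ) -> "RankMatrix":
        """Build from long-format rows (panelist_id, entity, rank)."""
        required = {"panelist_id", "entity", "rank"}
        if not required.issubset(frame.columns):
            raise SchemaError(
                f"long rank table needs columns {sorted(required)}, "
                f"got {list(frame.columns)}"
            )
        wide = frame.pivot(index="panelist_id", columns="entity", values="rank")
        return cls(wide, level=level, group_key=group_key)


def aggregate_median_ranks(matrix: RankMatrix) -> dict:
    """Per-entity median rank over panelists.

    The median of an even panel is the mean of the two central order
    statistics, so half-integer medians are possible (and are what the
    published weight table requires).
    """
    med = matrix.ranks.median(axis=0)
    return {entity: float(m) for entity, m in med.items()}


def rank_to_scores(median_ranks: Mapping, n: int) -> dict:
    """Convert median ranks to importance scores: score = (N+1) - rank.

    Rank 1 (most important of N entities) maps to score N; rank N maps to
    1. Raises :class:`DomainError` for a rank outside [1, N].
    """
    scores = {}
    for entity, rank in median_ranks.items():
        if not 1.0 <= float(rank) <= float(n):
            raise DomainError(
                f"entity {entity!r}: median rank {rank} outside [1, {n}]"
            )
        scores[entity] = float(n + 1) - float(rank)
    return scores


@dataclass(frozen=True)
class WeightDerivation:
    """One level of the rank-sum chain: medians -> scores -> weights."""

    median_ranks: Mapping
    importance_scores: Mapping
    weights: Mapping


@dataclass(frozen=True)
class FinalWeights:
    """Full two-level derivation and the resulting final item weights."""

    category_level: WeightDerivation
    item_levels: Mapping[Hashable, WeightDerivation]
    final_weights: Mapping
    final_weights_4dp: Mapping


def _normalize(scores: Mapping) -> dict:
    total = float(sum(scores.values()))
    if total <= 0:
        raise DomainError("importance scores must have a positive sum")
    return {k: float(v) / total for k, v in scores.items()}


def round_weight(value: float, ndigits: int = 4) -> float:
    """Round to ``ndigits`` decimals, halves away from zero.

    Matches the published table's display convention; fixed explicitly so
    boundary halves are deterministic across platforms.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _level_derivation(medians: Mapping) -> WeightDerivation:
    n = len(medians)
    scores = rank_to_scores(medians, n)
    return WeightDerivation(
        median_ranks=dict(medians),
        importance_scores=scores,
        weights=_normalize(scores),
    )


def _medians_of(source: Union[RankMatrix, Mapping]) -> Mapping:
    if isinstance(source, RankMatrix):
        return aggregate_median_ranks(source)
    return source


def derive_weight_table(
    category_ranks: Union[RankMatrix, Mapping],
    item_ranks: Mapping[Hashable, Union[RankMatrix, Mapping]],
) -> FinalWeights:
    """Run the full rank-sum chain to final item weights.

    ``category_ranks`` is a category-level rank matrix or a precomputed
    mapping of category -> median rank; ``item_ranks`` maps each category
    to its item-level matrix or median mapping. Scores at each level are
    (N+1) - median and are rescaled to sum to 1; an item's final weight is
    its category weight times its within-category weight, so the final
    weights across all items sum to 1 (up to float rounding).

    Raises :class:`SchemaError` if the category sets of the two levels
    differ, or an item key appears under two categories.
    """
    cat_medians = _medians_of(category_ranks)
    if set(cat_medians) != set(item_ranks):
        raise SchemaError(
            "category sets differ between the category level "
            f"({sorted(map(str, cat_medians))}) and the item level "
            f"({sorted(map(str, item_ranks))})"
        )
    category_level = _level_derivation(cat_medians)
    item_levels: dict = {}
    final: dict = {}
    for cat, source in item_ranks.items():
        level = _level_derivation(_medians_of(source))
        item_levels[cat] = level
        cat_weight = category_level.weights[cat]
        for item_key, w in level.weights.items():
            if item_key in final:
                raise SchemaError(
                    f"item key {item_key!r} appears in more than one category"
                )
            final[item_key] = cat_weight * w
    return FinalWeights(
        category_level=category_level,
        item_levels=item_levels,
        final_weights=final,
        final_weights_4dp={k: round_weight(v) for k, v in final.items()},
    )


# ---------------------------------------------------------------------------
# Feasibility of a median vector for an actual even panel
# ---------------------------------------------------------------------------

def _central_pairs(target: float, n_entities: int) -> list[tuple[int, int]]:
    """Integer pairs (a, b), a <= b, a + b = 2*target, within [1, N];
    tightest (closest to the target) first."""
    total = int(round(2 * target))
    pairs = []
    for a in range(1, n_entities + 1):
        b = total - a
        if a <= b <= n_entities:
            pairs.append((a, b))
    pairs.sort(key=lambda ab: ab[1] - ab[0])
    return pairs


def _hall_feasible(
    pairs: Sequence[tuple[int, int]], n_panelists: int, n_entities: int
) -> bool:
    """Exact feasibility of rank-column multisets with the given central
    order-statistic pairs.

    Each column needs m = n/2 values in [1, a] (largest exactly a) and m
    in [b, N] (smallest exactly b); each rank value has n copies in total
    (one per panelist). After reserving the forced a and b copies, the
    remaining fills form a transportation problem whose demand supports
    are prefixes [1, a] and suffixes [b, N]; Hall's condition then reduces
    to budget checks over every disjoint (prefix, suffix) split.
    """
    n, big_n = n_panelists, n_entities
    m = n // 2
    supply = [n] * (big_n + 1)  # 1-based
    for a, b in pairs:
        supply[a] -= 1
        supply[b] -= 1
        if supply[a] < 0 or supply[b] < 0:
            return False
    prefix = np.concatenate([[0], np.cumsum(supply[1:])])
    total = prefix[big_n]
    fill = m - 1
    if fill == 0:
        return total == 0  # forced copies must consume every rank exactly
    a_vals = np.array([p[0] for p in pairs])
    b_vals = np.array([p[1] for p in pairs])
    for k1 in range(0, big_n + 1):
        lo_demand = fill * int((a_vals <= k1).sum())
        for k2 in range(k1 + 1, big_n + 2):
            hi_demand = fill * int((b_vals >= k2).sum())
            available = prefix[k1] + (total - prefix[k2 - 1])
            if lo_demand + hi_demand > available:
                return False
    return True


def _find_central_pairs(
    targets: Sequence[float], n_panelists: int
) -> Optional[list[tuple[int, int]]]:
    """Central-pair assignment realizing the target medians, or None.

    Exhaustive over pair choices, so None certifies that no panel of
    ``n_panelists`` permutations has these column medians. Entities
    sharing a target are exchangeable, so the search enumerates pair
    multisets per distinct target (combinations with replacement) instead
    of the full product.
    """
    import itertools

    n_entities = len(targets)
    groups: dict[float, int] = {}
    for t in targets:
        groups[t] = groups.get(t, 0) + 1
    group_targets = list(groups)
    group_options = []
    for t in group_targets:
        options = _central_pairs(t, n_entities)
        if not options:
            return None
        group_options.append(
            list(itertools.combinations_with_replacement(options, groups[t]))
        )
    for combo in itertools.product(*group_options):
        assignment: dict[float, list[tuple[int, int]]] = {
            t: list(choice) for t, choice in zip(group_targets, combo)
        }
        flat: list[tuple[int, int]] = []
        cursor = {t: 0 for t in group_targets}
        for t in targets:
            flat.append(assignment[t][cursor[t]])
            cursor[t] += 1
        if _hall_feasible(flat, n_panelists, n_entities):
            return flat
    return None


def median_vector_feasible(targets: Sequence[float], n_panelists: int) -> bool:
    """Whether an even panel of ``n_panelists`` strict rankings can have
    exactly these column medians."""
    return _find_central_pairs(list(targets), n_panelists) is not None


# ---------------------------------------------------------------------------
# Certification: recover a median-rank configuration from printed weights
# ---------------------------------------------------------------------------

def _half_int(x: float) -> float:
    """Nearest half-integer, halves rounded up (deterministic)."""
    return float(np.floor(2.0 * x + 0.5)) / 2.0


def _level_candidates(targets: Mapping, tol: float) -> Iterable[Mapping]:
    """Half-integer median vectors whose normalized rank-sum scores
    approximate ``targets`` (normalized weights at one level).

    Iterates candidate score sums S on the half-integer grid from N to N*N;
    for each S the unique score vector closest to S*targets is kept if it
    is self-consistent (scores within [1, N] and summing back to S).
    Ordered by increasing S, so the coarsest consistent configuration comes
    first; any scalar multiple would give identical weights.
    """
    n = len(targets)
    keys = list(targets)
    for s2 in range(2 * n, 2 * n * n + 1):  # S in halves
        s = s2 / 2.0
        scores = {k: _half_int(targets[k] * s) for k in keys}
        if any(not 1.0 <= v <= float(n) for v in scores.values()):
            continue
        if abs(sum(scores.values()) - s) > 1e-9:
            continue
        if any(abs(v / s - targets[k]) > tol for k, v in scores.items()):
            continue
        yield {k: float(n + 1) - v for k, v in scores.items()}


def invert_weights_to_ranks(
    instrument: Instrument, tol: float = 5e-5, panel_size: int = 42
) -> tuple[Mapping, Mapping[Hashable, Mapping]]:
    """Recover a half-integer median-rank configuration that reproduces an
    instrument's printed weights through the rank-sum chain.

    Returns ``(category_medians, item_medians)`` keyed by category name and
    item id, such that :func:`derive_weight_table` on them yields every
    final item weight within ``tol`` of the table value (default half a
    4-decimal ulp, so rounding recovers the printed numbers exactly).
    Search is a brute-force scan over half-integer medians; candidates
    that no even panel of ``panel_size`` strict rankings could actually
    produce as medians are rejected (scale-equivalent score vectors give
    identical weights, but only some correspond to realizable panels),
    and the first end-to-end-consistent configuration is returned.

    Raises :class:`CertificationError` when no configuration exists —
    which, for a table claimed to come from this derivation, indicates an
    inconsistent table (or a bug in the chain).
    """
    cat_targets = {c.name: c.weight for c in instrument.categories}
    # Relative tolerance for the category scan: a final-weight error of tol
    # on the largest member item bounds the category weight error loosely.
    for cat_medians in _level_candidates(cat_targets, tol=5e-3):
        if not median_vector_feasible(list(cat_medians.values()), panel_size):
            continue
        cat_weights = _level_derivation(cat_medians).weights
        item_medians: dict = {}
        ok = True
        for cat in instrument.categories:
            members = instrument.items_in(cat.category_id)
            cw = cat_weights[cat.name]
            targets = {i.item_id: i.weight / cw for i in members}
            found = None
            for cand in _level_candidates(targets, tol=5e-2):
                if not median_vector_feasible(list(cand.values()), panel_size):
                    continue
                within = _level_derivation(cand).weights
                if all(
                    abs(cw * within[i.item_id] - i.weight) <= tol
                    for i in members
                ):
                    found = cand
                    break
            if found is None:
                ok = False
                break
            item_medians[cat.name] = found
        if ok:
            derived = derive_weight_table(cat_medians, item_medians)
            if all(
                abs(derived.final_weights[i.item_id] - i.weight) <= tol
                for i in instrument.items
            ):
                return cat_medians, item_medians
    raise CertificationError(
        "no half-integer median-rank configuration reproduces the "
        f"instrument's weights within {tol}"
    )
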