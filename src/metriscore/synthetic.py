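"""Seeded synthetic Delphi votes, rank matrices, and study assessments.

Everything the scoring and weight-derivation pipelines consume can be
generated here, so every stage is testable without the study's raw panel
data (which is not distributed). Generators are deterministic under a
fixed seed.

The rank-matrix generator is *median-exact* by construction rather than by
rejection sampling. For an even panel of n = 2m rows, a column's median is
the mean of its two central order statistics, so hitting a target median t
means pinning those two values to integers (a, b) with a + b = 2t. The
generator searches the central-pair choices per entity, checks by a
Hall-type condition whether column value multisets with those central
pairs can be assembled from each rank value's n available copies, routes
the copies with a max-flow, and finally splits the column-count matrix
into n permutations (Birkhoff decomposition via repeated bipartite
matching). The search is exhaustive over central pairs, so a
:class:`~metriscore.errors.FeasibilityError` is a proof that no panel of
that size can realize the requested medians — not a sampling timeout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FeasibilityError
from .instrument import ApplicabilityProfile, Instrument, load_instrument, resolve_applicability
from .delphi import (
    RankMatrix,
    VoteTable,
    VOTE_LABELS,
    _find_central_pairs,
)
from .scoring import Assessment

__all__ = [
    "VoteSimConfig",
    "RankSimConfig",
    "generate_votes",
    "generate_rank_matrix",
    "generate_assessment",
]


@dataclass(frozen=True)
class VoteSimConfig:
    """Likert vote simulation: each (panelist, item) vote falls on the
    agree side with ``agree_prob``, the disagree side with
    ``disagree_prob``, and is neutral otherwise; within a side the strong
    and plain labels split 50/50 (consensus logic only sees sides, so the
    split is inert and fixed for determinism)."""

    n_panelists: int
    agree_prob: float
    disagree_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_panelists < 1:
            raise DomainError("n_panelists must be >= 1")
        if not (0.0 <= self.agree_prob <= 1.0 and 0.0 <= self.disagree_prob <= 1.0):
            raise DomainError("probabilities must be in [0, 1]")
        if self.agree_prob + self.disagree_prob > 1.0 + 1e-12:
            raise DomainError("agree_prob + disagree_prob must be <= 1")


@dataclass(frozen=True)
class RankSimConfig:
    """Rank-matrix simulation targeting exact per-entity medians.

    ``target_medians`` maps entity -> integer or half-integer median in
    [1, N]; ``n_panelists`` must be even (half-integer medians only arise
    from even panels, whose median averages two order statistics)."""

    target_medians: Mapping[Hashable, float]
    n_panelists: int
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.target_medians)
        if n == 0:
            raise DomainError("target_medians must not be empty")
        if self.n_panelists < 2 or self.n_panelists % 2:
            raise DomainError("n_panelists must be an even count >= 2")
        for entity, t in self.target_medians.items():
            if not 1.0 <= float(t) <= float(n):
                raise DomainError(
                    f"entity {entity!r}: target median {t} outside [1, {n}]"
                )
            if float(2 * t) != int(2 * t):
                raise DomainError(
                    f"entity {entity!r}: target median {t} is not an "
                    "integer or half-integer"
                )


def generate_votes(config: VoteSimConfig, item_keys: Sequence[str]) -> VoteTable:
    """Simulate one voting round over ``item_keys``.

    Independent trinomial draw per (panelist, item); bit-reproducible for a
    fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    p = [
        config.agree_prob / 2.0,
        config.agree_prob / 2.0,
        max(0.0, 1.0 - config.agree_prob - config.disagree_prob),
        config.disagree_prob / 2.0,
        config.disagree_prob / 2.0,
    ]
    p = np.asarray(p) / np.sum(p)
    rows = []
    for panelist in range(1, config.n_panelists + 1):
        draws = rng.choice(len(VOTE_LABELS), size=len(item_keys), p=p)
        for item_key, d in zip(item_keys, draws):
            rows.append(
                {
                    "panelist_id": f"P{panelist:03d}",
                    "item_key": str(item_key),
                    "vote": VOTE_LABELS[d],
                }
            )
    return VoteTable(pd.DataFrame(rows))


def _column_counts(
    pairs: Sequence[tuple[int, int]], n_panelists: int
) -> np.ndarray:
    """Route rank-value copies into column lower/upper parts by max-flow.

    Returns counts[i, v-1] = how many of column i's entries equal v. Called
    only with a Hall-feasible pair assignment, so the flow saturates.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_flow

    n, big_n = n_panelists, len(pairs)
    m = n // 2
    fill = m - 1
    counts = np.zeros((big_n, big_n), dtype=int)
    supply = np.full(big_n + 1, n)
    for i, (a, b) in enumerate(pairs):
        counts[i, a - 1] += 1
        counts[i, b - 1] += 1
        supply[a] -= 1
        supply[b] -= 1
    if fill == 0:
        return counts
    # nodes: 0 source; 1..N values; then lo_i, hi_i per column; last sink
    lo0 = big_n + 1
    hi0 = lo0 + big_n
    sink = hi0 + big_n
    rows, cols, caps = [], [], []
    for v in range(1, big_n + 1):
        rows.append(0), cols.append(v), caps.append(int(supply[v]))
    for i, (a, b) in enumerate(pairs):
        for v in range(1, a + 1):
            rows.append(v), cols.append(lo0 + i), caps.append(fill)
        for v in range(b, big_n + 1):
            rows.append(v), cols.append(hi0 + i), caps.append(fill)
        rows.append(lo0 + i), cols.append(sink), caps.append(fill)
        rows.append(hi0 + i), cols.append(sink), caps.append(fill)
    graph = csr_matrix(
        (caps, (rows, cols)), shape=(sink + 1, sink + 1), dtype=np.int32
    )
    result = maximum_flow(graph, 0, sink)
    assert result.flow_value == 2 * fill * big_n, "flow must saturate (Hall-checked)"
    flow = result.flow.toarray()
    for i in range(big_n):
        for v in range(1, big_n + 1):
            counts[i, v - 1] += flow[v, lo0 + i] + flow[v, hi0 + i]
    return counts


def _extract_rows(
    counts: np.ndarray, n_panelists: int, rng: np.random.Generator
) -> list[list[int]]:
    """Split a doubly n-regular column/value count matrix into n
    permutations (Birkhoff decomposition by repeated Kuhn matching, with
    seeded neighbor order so rows vary between equivalent solutions)."""
    big_n = counts.shape[0]
    remaining = counts.copy()
    rows = []
    for _ in range(n_panelists):
        match_of_col = [-1] * big_n  # column -> value index
        match_of_val = [-1] * big_n

        def try_augment(col: int, seen: list[bool]) -> bool:
            values = [v for v in range(big_n) if remaining[col, v] > 0]
            rng.shuffle(values)
            for v in values:
                if seen[v]:
                    continue
                seen[v] = True
                if match_of_val[v] == -1 or try_augment(match_of_val[v], seen):
                    match_of_val[v] = col
                    match_of_col[col] = v
                    return True
            return False

        for col in range(big_n):
            assert try_augment(col, [False] * big_n), (
                "regular count matrix always admits a perfect matching"
            )
        for col, v in enumerate(match_of_col):
            remaining[col, v] -= 1
        rows.append([v + 1 for v in match_of_col])
    return rows


def generate_rank_matrix(
    config: RankSimConfig,
    level: str = "category",
    group_key: str = "",
) -> RankMatrix:
    """Build a panelist-by-entity rank matrix hitting the target medians
    exactly.

    Every row is a permutation of 1..N and every column's median equals
    its target by construction (the two central order statistics of each
    column are pinned to an integer pair summing to twice the target).
    Seeded randomization varies the rows wherever more than one matrix
    realizes the targets.

    Raises :class:`FeasibilityError` when no panel of this size can
    realize the target vector (e.g. two entities both targeted at median
    1) — the search over central order statistics is exhaustive, so this
    is a certificate of impossibility, not a sampling failure.
    """
    entities = list(config.target_medians)
    targets = [float(config.target_medians[e]) for e in entities]
    pairs = _find_central_pairs(targets, config.n_panelists)
    if pairs is None:
        raise FeasibilityError(
            f"no {config.n_panelists}-panelist rank matrix has column "
            f"medians {dict(config.target_medians)}"
        )
    counts = _column_counts(pairs, config.n_panelists)
    rng = np.random.default_rng(config.seed)
    rows = _extract_rows(counts, config.n_panelists, rng)
    rng.shuffle(rows)
    index = [f"P{k + 1:03d}" for k in range(config.n_panelists)]
    frame = pd.DataFrame(rows, index=index, columns=entities)
    frame.index.name = "panelist_id"
    return RankMatrix(frame, level=level, group_key=group_key)  # type: ignore[arg-type]


def generate_assessment(
    profile: ApplicabilityProfile,
    fulfill_prob: float,
    seed: int = 0,
    study_id: str = "synthetic",
    instrument: Optional[Instrument] = None,
) -> Assessment:
    """Simulate one study assessment under ``profile``.

    Applicable items are independently fulfilled with ``fulfill_prob``;
    inapplicable items are marked not_applicable, so the result always
    passes scoring validation.
    """
    if not 0.0 <= fulfill_prob <= 1.0:
        raise DomainError(f"fulfill_prob must be in [0, 1], got {fulfill_prob}")
    inst = instrument if instrument is not None else load_instrument()
    applicable = resolve_applicability(inst, profile)
    rng = np.random.default_rng(seed)
    statuses = {}
    for item in inst.items:
        if item.item_id not in applicable:
            statuses[item.item_id] = "not_applicable"
        else:
            statuses[item.item_id] = (
                "fulfilled" if rng.random() < fulfill_prob else "not_fulfilled"
            )
    return Assessment(study_id=study_id, profile=profile, statuses=statuses)
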