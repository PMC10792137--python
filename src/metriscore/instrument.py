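"""The METRICS instrument: data model, canonical weight table, applicability.

METRICS (METhodological RadiomICs Score) is a 30-item, 9-category weighted
checklist for appraising the methodological quality of radiomics studies.
Each item carries a weight (a unitless fraction; the 30 weights sum to 1)
derived from an expert-panel rank-sum procedure (see :mod:`metriscore.delphi`).

Seven items are *conditional*: they enter a study's score denominator only
when the study's pipeline triggers them. The trigger flags are collected in
:class:`ApplicabilityProfile`:

==========================  ==================================================
condition tag               applies when
==========================  ==================================================
``segmentation``            the study labels a region/volume of interest
                            (fine, pixel-based, or rough bounding-box)
``automated_segmentation``  segmentation is used *and* is fully automated
``handcrafted``             hand-crafted (engineered) features are used
``tabular``                 tabular feature data are used
``end_to_end_dl``           an end-to-end deep learning pipeline is used
==========================  ==================================================

A study mixing pipelines (e.g. hand-crafted radiomics compared against an
end-to-end network) simply sets every triggered flag; all matching
conditional items then apply simultaneously.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, Union

from .errors import IntegrityError, ProfileError, SchemaError

__all__ = [
    "Condition",
    "Item",
    "Category",
    "Instrument",
    "ApplicabilityProfile",
    "load_instrument",
    "resolve_applicability",
    "validate_profile",
    "iter_valid_profiles",
]

Condition = Literal[
    "always",
    "segmentation",
    "automated_segmentation",
    "handcrafted",
    "tabular",
    "end_to_end_dl",
]

_CONDITIONS: tuple[str, ...] = (
    "always",
    "segmentation",
    "automated_segmentation",
    "handcrafted",
    "tabular",
    "end_to_end_dl",
)

#: item_ids on which each non-trivial condition tag may legally appear
_CONDITION_ITEMS: dict[str, frozenset[int]] = {
    "segmentation": frozenset({8, 10}),
    "automated_segmentation": frozenset({9}),
    "handcrafted": frozenset({12}),
    "tabular": frozenset({14, 15, 16}),
    "end_to_end_dl": frozenset({17}),
}

N_ITEMS = 30
N_CATEGORIES = 9


@dataclass(frozen=True)
class Item:
    """One checklist item. ``weight`` is the canonical 4-decimal fraction."""

    item_id: int
    name: str
    category_id: int
    weight: float
    condition: Condition


@dataclass(frozen=True)
class Category:
    """A category; its weight is the sum of its member items' weights."""

    category_id: int
    name: str
    weight: float


@dataclass(frozen=True)
class Instrument:
    """The full instrument: 30 items in 9 categories, weights summing to 1.

    ``items`` and ``categories`` are in published table order. Categories
    sorted by descending weight (ties kept in table order) give the panel's
    importance order: study design first, open science last.
    """

    items: tuple[Item, ...]
    categories: tuple[Category, ...]
    version_tag: str = "metrics-v1"

    def item(self, item_id: int) -> Item:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise SchemaError(f"unknown item_id {item_id!r}") from None

    def category(self, category_id: int) -> Category:
        for c in self.categories:
            if c.category_id == category_id:
                return c
        raise SchemaError(f"unknown category_id {category_id!r}")

    def items_in(self, category_id: int) -> tuple[Item, ...]:
        return tuple(i for i in self.items if i.category_id == category_id)

    def categories_by_importance(self) -> tuple[Category, ...]:
        order = {c.category_id: k for k, c in enumerate(self.categories)}
        return tuple(
            sorted(
                self.categories,
                key=lambda c: (-c.weight, order[c.category_id]),
            )
        )

    @property
    def item_ids(self) -> tuple[int, ...]:
        return tuple(i.item_id for i in self.items)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_by_id", {i.item_id: i for i in self.items}
        )

    def to_json(self) -> str:
        """The canonical table as JSON (same content as the packaged CSV)."""
        return json.dumps(
            {
                "version_tag": self.version_tag,
                "items": [
                    {
                        "item_id": i.item_id,
                        "category_id": i.category_id,
                        "category_name": self.category(i.category_id).name,
                        "item_name": i.name,
                        "weight": i.weight,
                        "condition": i.condition,
                    }
                    for i in self.items
                ],
            },
            indent=2,
        )


@dataclass(frozen=True)
class ApplicabilityProfile:
    """Pipeline flags for one study; determines the applicable item set.

    Hard invariants (violations raise :class:`ProfileError`):

    * fully automated segmentation implies segmentation is used;
    * at least one of hand-crafted features, tabular features, or an
      end-to-end deep learning pipeline is present — a study with none of
      the three has no radiomics pipeline to assess.
    """

    uses_segmentation: bool
    fully_automated_segmentation: bool
    uses_handcrafted_features: bool
    uses_tabular_features: bool
    uses_end_to_end_dl: bool

    def __post_init__(self) -> None:
        if self.fully_automated_segmentation and not self.uses_segmentation:
            raise ProfileError(
                "fully_automated_segmentation=True requires "
                "uses_segmentation=True"
            )
        if not (
            self.uses_handcrafted_features
            or self.uses_tabular_features
            or self.uses_end_to_end_dl
        ):
            raise ProfileError(
                "at least one of uses_handcrafted_features, "
                "uses_tabular_features, uses_end_to_end_dl must be True"
            )

    def as_dict(self) -> dict[str, bool]:
        return {
            "uses_segmentation": self.uses_segmentation,
            "fully_automated_segmentation": self.fully_automated_segmentation,
            "uses_handcrafted_features": self.uses_handcrafted_features,
            "uses_tabular_features": self.uses_tabular_features,
            "uses_end_to_end_dl": self.uses_end_to_end_dl,
        }


def _packaged_table() -> Path:
    return Path(
        str(importlib.resources.files("metriscore").joinpath("data/metrics_v1.csv"))
    )


_REQUIRED_COLUMNS = (
    "item_id",
    "category_id",
    "category_name",
    "item_name",
    "weight",
    "condition",
)


def load_instrument(
    source: Optional[Union[str, Path]] = None,
    version_tag: str = "metrics-v1",
) -> Instrument:
    """Load and validate an instrument table.

    Without ``source``, the packaged canonical METRICS table is used. A
    custom table must be a CSV with columns
    ``item_id, category_id, category_name, item_name, weight, condition``
    and must satisfy every structural invariant: 30 items, 9 categories,
    positive weights, the printed 4-decimal weights summing to exactly
    1.0000, and conditionality tags only on the items that may carry them.

    Raises
    ------
    SchemaError
        Malformed rows/columns (the message names the offending row).
    IntegrityError
        Cardinality or weight-conservation violations.
    """
    path = Path(source) if source is not None else _packaged_table()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_REQUIRED_COLUMNS).issubset(
            reader.fieldnames
        ):
            missing = set(_REQUIRED_COLUMNS) - set(reader.fieldnames or [])
            raise SchemaError(
                f"{path}: missing required columns {sorted(missing)}"
            )
        rows = list(reader)

    items: list[Item] = []
    weights_dec: list[Decimal] = []
    cat_names: dict[int, str] = {}
    for lineno, row in enumerate(rows, start=2):
        try:
            item_id = int(row["item_id"])
            category_id = int(row["category_id"])
            weight_dec = Decimal(row["weight"])
            condition = row["condition"].strip()
        except (ValueError, ArithmeticError) as exc:
            raise SchemaError(f"{path} row {lineno}: {exc}") from None
        if condition not in _CONDITIONS:
            raise SchemaError(
                f"{path} row {lineno}: unknown condition {condition!r}"
            )
        if weight_dec <= 0:
            raise SchemaError(
                f"{path} row {lineno}: weight must be > 0, got {weight_dec}"
            )
        if condition != "always" and item_id not in _CONDITION_ITEMS[condition]:
            raise IntegrityError(
                f"{path} row {lineno}: condition {condition!r} may not "
                f"appear on item {item_id}"
            )
        prior = cat_names.setdefault(category_id, row["category_name"])
        if prior != row["category_name"]:
            raise SchemaError(
                f"{path} row {lineno}: category {category_id} renamed "
                f"{prior!r} -> {row['category_name']!r}"
            )
        weights_dec.append(weight_dec)
        items.append(
            Item(
                item_id=item_id,
                name=row["item_name"],
                category_id=category_id,
                weight=float(weight_dec),
                condition=condition,  # type: ignore[arg-type]
            )
        )

    if len(items) != N_ITEMS:
        raise IntegrityError(
            f"{path}: expected {N_ITEMS} items, found {len(items)}"
        )
    if sorted(i.item_id for i in items) != list(range(1, N_ITEMS + 1)):
        raise IntegrityError(f"{path}: item_id must cover 1..{N_ITEMS} exactly")
    if len(cat_names) != N_CATEGORIES:
        raise IntegrityError(
            f"{path}: expected {N_CATEGORIES} categories, found {len(cat_names)}"
        )
    total = sum(weights_dec)
    if total != Decimal("1.0000"):
        raise IntegrityError(
            f"{path}: item weights must sum to exactly 1.0000, got {total}"
        )

    categories = tuple(
        Category(
            category_id=cid,
            name=cat_names[cid],
            weight=float(
                sum(w for i, w in zip(items, weights_dec) if i.category_id == cid)
            ),
        )
        for cid in sorted(cat_names)
    )
    return Instrument(items=tuple(items), categories=categories, version_tag=version_tag)


def _item_applies(condition: str, profile: ApplicabilityProfile) -> bool:
    if condition == "always":
        return True
    if condition == "segmentation":
        return profile.uses_segmentation
    if condition == "automated_segmentation":
        return profile.uses_segmentation and profile.fully_automated_segmentation
    if condition == "handcrafted":
        return profile.uses_handcrafted_features
    if condition == "tabular":
        return profile.uses_tabular_features
    if condition == "end_to_end_dl":
        return profile.uses_end_to_end_dl
    raise SchemaError(f"unknown condition {condition!r}")


def resolve_applicability(
    instrument: Instrument, profile: ApplicabilityProfile
) -> frozenset[int]:
    """Item ids applicable to a study with the given pipeline profile.

    The 22 unconditional items are always included; each conditional item is
    included iff its trigger flag(s) are set. Turning any flag on can only
    grow the set (applicability is monotone in the profile).
    """
    return frozenset(
        i.item_id for i in instrument.items if _item_applies(i.condition, profile)
    )


def validate_profile(profile: ApplicabilityProfile) -> list[str]:
    """Soft warnings for unusual but permitted flag combinations.

    Hard invariant violations are raised by :class:`ApplicabilityProfile`
    itself; this reports only advisory oddities. Currently one: a
    hand-crafted pipeline without tabular features — hand-crafted feature
    extraction normally yields a tabular feature matrix, so items 14-16
    would usually be expected to apply.
    """
    warnings: list[str] = []
    if profile.uses_handcrafted_features and not profile.uses_tabular_features:
        warnings.append(
            "uses_handcrafted_features=True with uses_tabular_features=False: "
            "hand-crafted pipelines normally produce tabular feature data, so "
            "the tabular-data items would usually apply"
        )
    return warnings


def iter_valid_profiles() -> Iterator[ApplicabilityProfile]:
    """Enumerate all applicability profiles satisfying the hard invariants.

    There are 21: three legal (segmentation, fully-automated) combinations
    times the seven non-empty subsets of the three pipeline flags.
    """
    for seg, auto in ((False, False), (True, False), (True, True)):
        for hc in (False, True):
            for tab in (False, True):
                for e2e in (False, True):
                    if not (hc or tab or e2e):
                        continue
                    yield ApplicabilityProfile(
                        uses_segmentation=seg,
                        fully_automated_segmentation=auto,
                        uses_handcrafted_features=hc,
                        uses_tabular_features=tab,
                        uses_end_to_end_dl=e2e,
                    )
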