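"""Reading and writing assessment, vote, and rank files.

Formats
-------
* Assessment documents: JSON or YAML with the shape
  ``{"study_id": ..., "profile": {<5 flags>}, "statuses": {"1": "fulfilled", ...}}``
  (schema shipped as ``data/assessment.schema.json``).
* Batch CSV: one row per study; columns ``study_id``, the five profile
  flags, and ``i01``..``i30`` holding ``F`` (fulfilled), ``N`` (not
  fulfilled) or ``NA`` (not applicable).
* Rank CSV (long): columns ``panelist_id, level, group_key, entity, rank``
  with ``level`` in {category, item}; category-level rows leave
  ``group_key`` empty, item-level rows put the category name there.
* Results: CSV table, JSON, or a per-study markdown report mirroring the
  published table layout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Literal, Mapping, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .delphi import RankMatrix
from .errors import SchemaError
from .instrument import ApplicabilityProfile, Instrument
from .scoring import Assessment, ScoreResult

__all__ = [
    "read_assessment",
    "read_assessment_batch_csv",
    "read_assessments",
    "read_rank_csv",
    "assessment_to_json",
    "export_assessment_schema",
    "score_result_to_dict",
    "render_markdown_report",
]

_STATUS_CODES = {"F": "fulfilled", "N": "not_fulfilled", "NA": "not_applicable"}
_CODE_OF_STATUS = {v: k for k, v in _STATUS_CODES.items()}
_FLAGS = (
    "uses_segmentation",
    "fully_automated_segmentation",
    "uses_handcrafted_features",
    "uses_tabular_features",
    "uses_end_to_end_dl",
)


class ProfileDocument(BaseModel):
    model_config = ConfigDict(extra="forbid")
    uses_segmentation: bool
    fully_automated_segmentation: bool
    uses_handcrafted_features: bool
    uses_tabular_features: bool
    uses_end_to_end_dl: bool


class AssessmentDocument(BaseModel):
    """File-level schema of one study assessment."""

    model_config = ConfigDict(extra="forbid")
    study_id: str
    profile: ProfileDocument
    statuses: Dict[str, Literal["fulfilled", "not_fulfilled", "not_applicable"]]


def _document_to_assessment(doc: AssessmentDocument) -> Assessment:
    profile = ApplicabilityProfile(**doc.profile.model_dump())
    statuses = {}
    for key, status in doc.statuses.items():
        try:
            item_id = int(key)
        except ValueError:
            raise SchemaError(f"statuses key {key!r} is not an item id") from None
        statuses[item_id] = status
    return Assessment(study_id=doc.study_id, profile=profile, statuses=statuses)


def read_assessment(path: Union[str, Path]) -> Assessment:
    """Parse one JSON (``.json``) or YAML (``.yaml``/``.yml``) assessment.

    Schema violations raise :class:`SchemaError` with the JSON-pointer-like
    location of the offending field.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise SchemaError(f"{path}: unparseable document: {exc}") from None
    try:
        doc = AssessmentDocument.model_validate(payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        pointer = "/" + "/".join(str(p) for p in first["loc"])
        raise SchemaError(f"{path}: {pointer}: {first['msg']}") from None
    return _document_to_assessment(doc)


def _parse_flag(value, column: str, row: int) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "t", "1", "yes", "y"):
        return True
    if text in ("false", "f", "0", "no", "n"):
        return False
    raise SchemaError(f"row {row}: column {column!r}: not a boolean: {value!r}")


def read_assessment_batch_csv(path: Union[str, Path]) -> list[Assessment]:
    """Parse a batch CSV (one study per row) into assessments, in row order."""
    # keep_default_na: the status code "NA" is data, not a missing value
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    item_cols = [f"i{k:02d}" for k in range(1, 31)]
    required = {"study_id", *_FLAGS, *item_cols}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for idx, row in frame.iterrows():
        rowno = int(idx) + 2  # header is line 1
        profile = ApplicabilityProfile(
            **{flag: _parse_flag(row[flag], flag, rowno) for flag in _FLAGS}
        )
        statuses = {}
        for k, col in enumerate(item_cols, start=1):
            code = str(row[col]).strip().upper()
            if code not in _STATUS_CODES:
                raise SchemaError(
                    f"{path} row {rowno}: column {col!r}: expected F/N/NA, "
                    f"got {row[col]!r}"
                )
            statuses[k] = _STATUS_CODES[code]
        out.append(
            Assessment(study_id=str(row["study_id"]), profile=profile, statuses=statuses)
        )
    return out


def read_assessments(path: Union[str, Path]) -> list[Assessment]:
    """Read a directory of JSON/YAML assessments (sorted by filename) or a
    single batch CSV / assessment document, whichever ``path`` is."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p
            for p in path.iterdir()
            if p.suffix.lower() in (".json", ".yaml", ".yml")
        )
        if not files:
            raise SchemaError(f"{path}: no assessment files found")
        return [read_assessment(p) for p in files]
    if path.suffix.lower() == ".csv":
        return read_assessment_batch_csv(path)
    return [read_assessment(path)]


def read_rank_csv(
    path: Union[str, Path],
) -> tuple[RankMatrix, dict[str, RankMatrix]]:
    """Parse a long-format rank CSV into the category-level matrix and the
    per-category item-level matrices."""
    frame = pd.read_csv(path, dtype={"panelist_id": str, "entity": str})
    required = {"panelist_id", "level", "group_key", "entity", "rank"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    bad = ~frame["level"].isin(("category", "item"))
    if bad.any():
        rows = [int(i) + 2 for i in frame.index[bad][:5]]
        raise SchemaError(
            f"{path}: rows {rows}: level must be 'category' or 'item'"
        )
    cat_rows = frame[frame["level"] == "category"]
    if cat_rows.empty:
        raise SchemaError(f"{path}: no category-level rows")
    category = RankMatrix.from_long(cat_rows, level="category")
    items: dict[str, RankMatrix] = {}
    for group, sub in frame[frame["level"] == "item"].groupby("group_key"):
        items[str(group)] = RankMatrix.from_long(
            sub, level="item", group_key=str(group)
        )
    return category, items


def assessment_to_json(assessment: Assessment) -> str:
    doc = {
        "study_id": assessment.study_id,
        "profile": assessment.profile.as_dict(),
        "statuses": {
            str(k): assessment.statuses[k] for k in sorted(assessment.statuses)
        },
    }
    return json.dumps(doc, indent=2)


def export_assessment_schema() -> dict:
    """JSON-Schema for the assessment document format (also shipped as
    ``data/assessment.schema.json``)."""
    return AssessmentDocument.model_json_schema()


def score_result_to_dict(result: ScoreResult) -> dict:
    return {
        "study_id": result.study_id,
        "percentage": result.percentage,
        "quality_category": result.quality_category,
        "achieved_weight": result.achieved_weight,
        "achievable_weight": result.achievable_weight,
        "per_item_contribution": {
            str(k): v for k, v in sorted(result.per_item_contribution.items())
        },
    }


def render_markdown_report(
    instrument: Instrument, assessment: Assessment, result: ScoreResult
) -> str:
    """Per-study markdown report mirroring the instrument's table layout."""
    lines = [
        f"# METRICS report — {result.study_id}",
        "",
        f"**Score: {result.percentage:.2f}% — {result.quality_category}**",
        "",
        f"Achieved weight {result.achieved_weight:.4f} of achievable "
        f"{result.achievable_weight:.4f} "
        f"(instrument {instrument.version_tag}).",
        "",
        "| Category | # | Item | Weight | Status | Contribution |",
        "|---|---|---|---|---|---|",
    ]
    last_cat = None
    for item in instrument.items:
        cat = instrument.category(item.category_id).name
        shown_cat = cat if cat != last_cat else ""
        last_cat = cat
        status = assessment.statuses[item.item_id]
        contribution = result.per_item_contribution.get(item.item_id)
        contribution_txt = "—" if contribution is None else f"{contribution:.4f}"
        lines.append(
            f"| {shown_cat} | {item.item_id} | {item.name} | "
            f"{item.weight:.4f} | {_CODE_OF_STATUS[status]} | {contribution_txt} |"
        )
    lines += [
        "",
        "Status codes: F fulfilled, N not fulfilled, NA not applicable.",
        "",
    ]
    return "\n".join(lines)
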