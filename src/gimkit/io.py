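"""Readers and writers for the toolkit's file formats.

Item bank CSV: ``item_id,subject_cluster,answer_key,difficulty,max_score``
(the last two optional; a bank without difficulties is uncalibrated).
Response CSV: a ``candidate_id`` column followed by one column per item id,
holding raw option codes (blank = unanswered).  Map reports are versioned
JSON documents (``"gim_schema": 1``) that round-trip losslessly.
All CSV is comma-separated UTF-8 with a header row.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import (
    BlankPolicy,
    CalibrationConstraint,
    ClusterGroup,
    FormatError,
    GimLayout,
    ItemBank,
    ItemRecord,
    PlacedItem,
    Quadrant,
    RawResponseTable,
    ResponseMatrix,
    Side,
    SubjectFlag,
    ValidationError,
)
from .pcm import PcmItem

logger = logging.getLogger(__name__)

GIM_SCHEMA_VERSION = 1

_BANK_REQUIRED = ("item_id", "subject_cluster", "answer_key")
_BANK_KNOWN = _BANK_REQUIRED + ("difficulty", "max_score")


def read_item_bank(path: Union[str, Path], format: Optional[str] = None) -> ItemBank:
    """Read an item bank from CSV or JSON (inferred from the suffix).

    Duplicate item ids raise a :class:`FormatError` naming the id; unknown
    columns are ignored with a logged warning; a missing ``difficulty``
    column yields an uncalibrated bank.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        payload = json.loads(path.read_text())
        constraint = CalibrationConstraint(payload.get("calibration_constraint", "mean_zero"))
        rows = payload["items"]
        df = pd.DataFrame(rows)
    elif fmt == "csv":
        constraint = CalibrationConstraint.MEAN_ZERO
        df = pd.read_csv(path, dtype={"item_id": str, "subject_cluster": str})
    else:
        raise FormatError(f"unknown item bank format {fmt!r}")

    missing = [c for c in _BANK_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"item bank {path} missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in _BANK_KNOWN]
    if unknown:
        logger.warning("item bank %s: ignoring unknown columns %s", path, unknown)

    ids = df["item_id"].astype(str).tolist()
    dup = pd.Series(ids)[pd.Series(ids).duplicated()]
    if not dup.empty:
        raise FormatError(f"duplicate item_id {dup.iloc[0]!r} in {path}")

    items = []
    for _, row in df.iterrows():
        diff = row.get("difficulty")
        if diff is not None and (isinstance(diff, float) and np.isnan(diff)):
            diff = None
        items.append(ItemRecord(
            item_id=str(row["item_id"]),
            subject_cluster=str(row["subject_cluster"]),
            answer_key=int(row["answer_key"]),
            difficulty=None if diff is None else float(diff),
            max_score=int(row.get("max_score", 1)) if not pd.isna(row.get("max_score", 1)) else 1,
        ))
    return ItemBank(items=items, calibration_constraint=constraint)


def write_item_bank(bank: ItemBank, path: Union[str, Path]) -> None:
    path = Path(path)
    rows = [
        {
            "item_id": it.item_id,
            "subject_cluster": it.subject_cluster,
            "answer_key": it.answer_key,
            "difficulty": it.difficulty,
            "max_score": it.max_score,
        }
        for it in bank.items
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(
            {"calibration_constraint": bank.calibration_constraint.value, "items": rows},
            indent=2))
    else:
        pd.DataFrame(rows).to_csv(path, index=False)


def read_pcm_bank(path: Union[str, Path]) -> list[PcmItem]:
    """Read a polytomous bank CSV: item_id,subject_cluster,max_score,threshold_1..m."""
    df = pd.read_csv(path, dtype={"item_id": str, "subject_cluster": str})
    items = []
    for _, row in df.iterrows():
        m = int(row["max_score"])
        thr = [float(row[f"threshold_{k}"]) for k in range(1, m + 1)]
        items.append(PcmItem(item_id=str(row["item_id"]),
                             subject_cluster=str(row["subject_cluster"]),
                             thresholds=np.array(thr)))
    return items


def read_raw_responses(path: Union[str, Path]) -> RawResponseTable:
    """Read a raw response CSV (candidate_id then one column per item)."""
    df = pd.read_csv(path, dtype={"candidate_id": str})
    if "candidate_id" not in df.columns:
        raise FormatError(f"response table {path} has no candidate_id column")
    item_ids = [c for c in df.columns if c != "candidate_id"]
    options = []
    for _, row in df.iterrows():
        opts = []
        for iid in item_ids:
            v = row[iid]
            opts.append(None if pd.isna(v) else int(v))
        options.append(opts)
    return RawResponseTable(candidate_ids=df["candidate_id"].tolist(),
                            item_ids=item_ids, options=options)


def score_responses(raw: RawResponseTable, bank: ItemBank,
                    blank_policy: BlankPolicy = BlankPolicy.INCORRECT,
                    n_options: Optional[int] = None) -> ResponseMatrix:
    """Score raw option codes against the bank's answer keys.

    Score 1 where the chosen option equals the answer key, else 0.  Blanks
    score 0 under the default ``incorrect`` policy (an unanswered item in a
    supervised exam earns no credit); under ``missing`` they are flagged and
    excluded from facility denominators downstream.  When ``n_options`` is
    given, option codes outside 1..n_options raise a validation error
    listing every offending cell.
    """
    bank_ids = set(bank.item_ids)
    stray = [iid for iid in raw.item_ids if iid not in bank_ids]
    if stray:
        raise ValidationError(f"response columns not in bank: {stray}")
    keys = {it.item_id: it.answer_key for it in bank.items}

    if n_options is not None:
        bad = [
            (cid, iid, opt)
            for cid, row in zip(raw.candidate_ids, raw.options)
            for iid, opt in zip(raw.item_ids, row)
            if opt is not None and not (1 <= opt <= n_options)
        ]
        if bad:
            raise ValidationError(f"option codes outside 1..{n_options}: {bad}")

    n, m = len(raw.candidate_ids), len(raw.item_ids)
    scores = np.zeros((n, m), dtype=int)
    missing = np.zeros((n, m), dtype=bool)
    for i, row in enumerate(raw.options):
        for j, opt in enumerate(row):
            if opt is None:
                if blank_policy is BlankPolicy.MISSING:
                    missing[i, j] = True
                continue  # blank scores 0 either way
            scores[i, j] = int(opt == keys[raw.item_ids[j]])
    return ResponseMatrix(candidate_ids=list(raw.candidate_ids),
                          item_ids=list(raw.item_ids),
                          scores=scores, missing=missing)


def read_response_matrix(path: Union[str, Path]) -> ResponseMatrix:
    """Read an already-scored 0/1 response CSV."""
    df = pd.read_csv(path, dtype={"candidate_id": str})
    if "candidate_id" not in df.columns:
        raise FormatError(f"response matrix {path} has no candidate_id column")
    item_ids = [c for c in df.columns if c != "candidate_id"]
    return ResponseMatrix(candidate_ids=df["candidate_id"].tolist(),
                          item_ids=item_ids,
                          scores=df[item_ids].to_numpy(dtype=int))


def write_response_matrix(responses: ResponseMatrix, path: Union[str, Path]) -> None:
    df = pd.DataFrame(responses.scores, columns=responses.item_ids)
    df.insert(0, "candidate_id", responses.candidate_ids)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Map report JSON


def layout_to_dict(layout: GimLayout) -> dict:
    return {
        "gim_schema": GIM_SCHEMA_VERSION,
        "candidate_id": layout.candidate_id,
        "ability_line": layout.ability_line,
        "pass_line": layout.pass_line,
        "columns": list(layout.columns),
        "placed": [
            {
                "item_id": p.item_id,
                "subject_cluster": p.subject_cluster,
                "side": p.side.value,
                "y": p.y,
                "quadrant": None if p.quadrant is None else p.quadrant.value,
            }
            for p in layout.placed
        ],
        "groups": [
            {
                "subject_cluster": g.subject_cluster,
                "side": g.side.value,
                "member_ids": list(g.member_ids),
                "y": g.y,
                "count": g.count,
                "label": g.label,
            }
            for g in layout.groups
        ],
        "flags": {c: f.value for c, f in layout.flags.items()},
    }


def layout_from_dict(doc: dict) -> GimLayout:
    if doc.get("gim_schema") != GIM_SCHEMA_VERSION:
        raise FormatError(f"unsupported gim_schema {doc.get('gim_schema')!r}")
    placed = [
        PlacedItem(
            item_id=p["item_id"],
            subject_cluster=p["subject_cluster"],
            side=Side(p["side"]),
            y=float(p["y"]),
            quadrant=None if p["quadrant"] is None else Quadrant(p["quadrant"]),
        )
        for p in doc["placed"]
    ]
    groups = [
        ClusterGroup(
            subject_cluster=g["subject_cluster"],
            side=Side(g["side"]),
            member_ids=list(g["member_ids"]),
            y=float(g["y"]),
        )
        for g in doc["groups"]
    ]
    layout = GimLayout(
        candidate_id=doc["candidate_id"],
        ability_line=float(doc["ability_line"]),
        columns=list(doc["columns"]),
        placed=placed,
        groups=groups,
        flags={c: SubjectFlag(v) for c, v in doc["flags"].items()},
        pass_line=None if doc["pass_line"] is None else float(doc["pass_line"]),
    )
    layout.validate()
    return layout


def write_gim_report(layout: GimLayout, path: Union[str, Path]) -> None:
    """Write a map layout as versioned JSON; round-trips losslessly."""
    layout.validate()
    Path(path).write_text(json.dumps(layout_to_dict(layout), indent=2, sort_keys=True))


def read_gim_report(path: Union[str, Path]) -> GimLayout:
    return layout_from_dict(json.loads(Path(path).read_text()))


def write_person_estimates(estimates, path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "candidate_id": e.candidate_id,
                "raw_score": e.raw_score,
                "ability_logit": e.ability,
                "se": e.standard_error,
            }
            for e in estimates
        ]
    ).to_csv(path, index=False)
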