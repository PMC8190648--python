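"""Parallel corpus construction and data splits.

The translation corpus pairs each case's (possibly curated) source text
with the canonical description of its gold code, normalized the same
way so translation and matching operate in one text space. Splits
follow the study protocol: a calendar cutoff separates a temporal
holdout set (no leakage from future cases), and the remaining
development cases are split 80/20 into train/validation stratified by
code.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import CodeCatalog
from .preprocess import NormalizationLexicons, build_input, normalize

__all__ = [
    "OperativeCase",
    "ParallelPair",
    "SplitSpec",
    "cases_from_frame",
    "build_pairs",
    "date_split",
    "stratified_split",
    "write_parallel",
    "read_parallel",
]

# Target-side curation keeps surface form: no stopword removal or
# lemmatization, so the emitted sentences stay readable descriptions.
TARGET_STEPS = ("trim", "lowercase",)


@dataclass(frozen=True)
class OperativeCase:
    """One surgical record: texts, gold code, service date."""

    case_id: str
    date: dt.date
    procedure_text: str
    preop_diagnosis: str
    code: str


@dataclass(frozen=True)
class ParallelPair:
    """Source sentence paired with the gold code's canonical description."""

    source: str
    target: str
    code: str
    case_id: str


@dataclass(frozen=True)
class SplitSpec:
    """Holdout cutoff plus stratified train/validation parameters."""

    cutoff_date: dt.date
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be strictly between 0 and 1")


def _parse_date(value: object, case_id: str) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"case {case_id!r}: unparseable date {value!r}") from exc


def cases_from_frame(df: pd.DataFrame) -> list[OperativeCase]:
    """Build cases from a table with columns case_id, date,
    procedure_text, preop_diagnosis, code."""
    cases = []
    for row in df.itertuples(index=False):
        cid = str(row.case_id)
        cases.append(
            OperativeCase(
                case_id=cid,
                date=_parse_date(row.date, cid),
                procedure_text=str(row.procedure_text),
                preop_diagnosis=str(getattr(row, "preop_diagnosis", "") or ""),
                code=str(row.code).zfill(5),
            )
        )
    return cases


def normalize_target(term: str) -> str:
    """Canonical-description normalization: lowercase, punctuation
    stripped, whitespace collapsed (mirrors the source text space)."""
    return normalize(term, steps=TARGET_STEPS).joined


def build_pairs(
    cases: Sequence[OperativeCase],
    catalog: CodeCatalog,
    mode: str = "curated",
    lexicons: NormalizationLexicons | None = None,
) -> list[ParallelPair]:
    """Pair each case's source text with its code's normalized term.

    Cases must already be filtered against the catalog; an unknown
    code raises, naming the case.
    """
    pairs: list[ParallelPair] = []
    target_cache: dict[str, str] = {}
    for case in cases:
        if case.code not in catalog:
            raise KeyError(f"case {case.case_id!r}: code {case.code!r} not in catalog")
        if case.code not in target_cache:
            target_cache[case.code] = normalize_target(catalog.lookup(case.code))
        pairs.append(
            ParallelPair(
                source=build_input(
                    case.procedure_text, case.preop_diagnosis, mode, lexicons
                ),
                target=target_cache[case.code],
                code=case.code,
                case_id=case.case_id,
            )
        )
    return pairs


def date_split(
    cases: Sequence[OperativeCase], cutoff_date: dt.date
) -> tuple[list[OperativeCase], list[OperativeCase]]:
    """Partition cases at a calendar cutoff.

    Cases dated strictly before the cutoff form the development set;
    cases on or after it form the temporal holdout. Exhaustive and
    disjoint by construction.
    """
    development = [c for c in cases if c.date < cutoff_date]
    holdout = [c for c in cases if c.date >= cutoff_date]
    return development, holdout


def stratified_split(
    cases: Sequence[OperativeCase], val_fraction: float = 0.2, seed: int = 0
) -> tuple[list[OperativeCase], list[OperativeCase]]:
    """Split cases into train/validation stratified by code.

    Within each label the validation share differs from
    ``val_fraction`` by at most one case. Labels with a single case go
    to train so the model sees every label's target at least once.
    Deterministic given ``seed``; original case order is preserved in
    both outputs.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    by_code: dict[str, list[int]] = {}
    for i, case in enumerate(cases):
        by_code.setdefault(case.code, []).append(i)
    val_idx: set[int] = set()
    for code in sorted(by_code):
        idx = by_code[code]
        n = len(idx)
        if n < 2:
            continue
        n_val = min(int(round(val_fraction * n)), n - 1)
        chosen = rng.choice(len(idx), size=n_val, replace=False)
        val_idx.update(idx[j] for j in chosen)
    train = [c for i, c in enumerate(cases) if i not in val_idx]
    val = [c for i, c in enumerate(cases) if i in val_idx]
    return train, val


def write_parallel(pairs: Sequence[ParallelPair], prefix: str | Path) -> None:
    """Serialize a corpus as aligned .src/.tgt text files plus a
    JSON-lines sidecar carrying case_id and code."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.src", "w") as fs, open(
        f"{prefix}.tgt", "w"
    ) as ft, open(f"{prefix}.meta.jsonl", "w") as fm:
        for p in pairs:
            fs.write(p.source + "\n")
            ft.write(p.target + "\n")
            fm.write(json.dumps({"case_id": p.case_id, "code": p.code}) + "\n")


def read_parallel(prefix: str | Path) -> list[ParallelPair]:
    """Load a corpus written by :func:`write_parallel`."""
    prefix = Path(prefix)
    sources = Path(f"{prefix}.src").read_text().splitlines()
    targets = Path(f"{prefix}.tgt").read_text().splitlines()
    metas = [
        json.loads(line)
        for line in Path(f"{prefix}.meta.jsonl").read_text().splitlines()
    ]
    if not len(sources) == len(targets) == len(metas):
        raise ValueError("corpus files are not aligned")
    return [
        ParallelPair(source=s, target=t, code=m["code"], case_id=m["case_id"])
        for s, t, m in zip(sources, targets, metas)
    ]
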