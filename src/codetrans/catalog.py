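"""Code catalog: canonical descriptions and body-region categories.

A catalog maps each 5-character procedure code to exactly one canonical
description (its *preferred term*) and, optionally, to a body-region
category defined by inclusive code ranges (e.g. ``Head: 00100-00222``).
Case tables are filtered against the catalog before any modelling:
codes absent from the catalog are invalid, and codes flagged as
deprecated are dropped with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CodeEntry",
    "CodeCatalog",
    "CaseFilterReport",
    "CatalogError",
    "ANESTHESIA_BODY_REGIONS",
    "DEFAULT_DEPRECATED_CODES",
    "load_catalog",
    "save_catalog",
    "filter_cases",
]

#: Body-region categories keyed to inclusive code ranges, as used for
#: anesthesia procedure codes. Codes compare as zero-padded strings,
#: which coincides with numeric order for 5-digit codes.
ANESTHESIA_BODY_REGIONS: dict[str, tuple[str, str]] = {
    "Head": ("00100", "00222"),
    "Neck": ("00300", "00352"),
    "Thorax (chest and shoulder)": ("00400", "00474"),
    "Intrathoracic": ("00500", "00580"),
    "Spine and spinal cord": ("00600", "00670"),
    "Upper abdomen": ("00700", "00797"),
    "Lower abdomen": ("00800", "00882"),
    "Perineum": ("00902", "00952"),
    "Pelvis (except hip)": ("01112", "01173"),
    "Upper leg (except knee)": ("01200", "01274"),
    "Knee and popliteal area": ("01320", "01444"),
    "Lower leg (below knee)": ("01462", "01522"),
    "Shoulder and axilla": ("01610", "01680"),
    "Upper arm and elbow": ("01710", "01782"),
    "Forearm, wrist, and hand": ("01810", "01860"),
    "Radiological procedure": ("01916", "01936"),
    "Burn excisions or debridement": ("01951", "01953"),
    "Obstetric": ("01958", "01969"),
    "Other procedure": ("01990", "01999"),
}

#: Codes deprecated mid-study and replaced by finer-grained successors
#: (upper/lower gastrointestinal endoscopy). Supplied as configuration;
#: callers may pass any other set to :func:`filter_cases`.
DEFAULT_DEPRECATED_CODES: frozenset[str] = frozenset({"00740", "00810"})

UNCATEGORIZED = "uncategorized"


class CatalogError(ValueError):
    """Raised when a catalog violates its invariants."""


def _pad(code: str) -> str:
    return str(code).strip().zfill(5)


@dataclass(frozen=True)
class CodeEntry:
    """One catalog row: a code, its canonical description, its category."""

    code: str
    preferred_term: str
    category: str = UNCATEGORIZED

    def __post_init__(self) -> None:
        if not self.code or not str(self.code).strip():
            raise CatalogError("code must be non-empty")
        if not self.preferred_term or not self.preferred_term.strip():
            raise CatalogError(f"empty preferred term for code {self.code!r}")
        object.__setattr__(self, "code", _pad(self.code))


@dataclass
class CodeCatalog:
    """Ordered collection of code entries with a code -> term bijection."""

    entries: list[CodeEntry]
    category_ranges: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen_codes: set[str] = set()
        seen_terms: set[str] = set()
        for e in self.entries:
            if e.code in seen_codes:
                raise CatalogError(f"duplicate code {e.code!r} in catalog")
            if e.preferred_term in seen_terms:
                raise CatalogError(
                    f"duplicate preferred term {e.preferred_term!r} "
                    f"(code {e.code!r}); code->term must be a bijection"
                )
            seen_codes.add(e.code)
            seen_terms.add(e.preferred_term)
        self._by_code = {e.code: e for e in self.entries}
        ranges = sorted(self.category_ranges.items(), key=lambda kv: kv[1])
        for (_, (_, hi)), (label, (lo, _)) in zip(ranges, ranges[1:]):
            if lo <= hi:
                raise CatalogError(f"category ranges overlap at {label!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return _pad(code) in self._by_code

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.entries]

    @property
    def terms(self) -> list[str]:
        return [e.preferred_term for e in self.entries]

    def lookup(self, code: str) -> str:
        """Return the preferred term of ``code``; KeyError if absent."""
        return self._by_code[_pad(code)].preferred_term

    def category_of(self, code: str) -> str:
        """Body-region label of the range containing ``code``.

        Containment is checked on zero-padded string forms; a code
        outside every range maps to ``"uncategorized"`` (a value, not
        an error).
        """
        c = _pad(code)
        for label, (lo, hi) in self.category_ranges.items():
            if _pad(lo) <= c <= _pad(hi):
                return label
        return UNCATEGORIZED


@dataclass(frozen=True)
class CaseFilterReport:
    """Accounting of a case-table filtering pass."""

    retained: int
    excluded_invalid: int
    excluded_deprecated: int
    excluded_codes: list[tuple[str, str]]

    @property
    def total(self) -> int:
        return self.retained + self.excluded_invalid + self.excluded_deprecated


def load_catalog(
    path: str | Path,
    sep: str = "\t",
    category_ranges: Mapping[str, tuple[str, str]] | None = None,
) -> CodeCatalog:
    """Read a catalog from a delimited text file.

    The file must have a header with columns ``code`` and
    ``preferred_term``; a ``category`` column is optional. Entry order
    is file order. Violated invariants (duplicate code, duplicate or
    empty term) raise :class:`CatalogError` naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = {"code", "preferred_term"} - set(df.columns)
    if missing:
        raise CatalogError(f"catalog {path} missing columns: {sorted(missing)}")
    has_cat = "category" in df.columns
    entries = [
        CodeEntry(
            code=row.code,
            preferred_term=row.preferred_term,
            category=(row.category if has_cat and row.category else UNCATEGORIZED),
        )
        for row in df.itertuples(index=False)
    ]
    ranges = dict(category_ranges) if category_ranges is not None else {}
    if not ranges and has_cat:
        ranges = _ranges_from_entries(entries)
    return CodeCatalog(entries=entries, category_ranges=ranges)


def _ranges_from_entries(entries: Sequence[CodeEntry]) -> dict[str, tuple[str, str]]:
    """Recover per-category code ranges from labelled entries."""
    ranges: dict[str, tuple[str, str]] = {}
    for e in entries:
        if e.category == UNCATEGORIZED:
            continue
        lo, hi = ranges.get(e.category, (e.code, e.code))
        ranges[e.category] = (min(lo, e.code), max(hi, e.code))
    return ranges


def save_catalog(catalog: CodeCatalog, path: str | Path, sep: str = "\t") -> None:
    """Write a catalog as delimited text (code, preferred_term, category)."""
    df = pd.DataFrame(
        {
            "code": [e.code for e in catalog.entries],
            "preferred_term": [e.preferred_term for e in catalog.entries],
            "category": [e.category for e in catalog.entries],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def filter_cases(
    cases: pd.DataFrame,
    catalog: CodeCatalog,
    deprecated: Iterable[str] = DEFAULT_DEPRECATED_CODES,
) -> tuple[pd.DataFrame, CaseFilterReport]:
    """Drop cases whose code is invalid (absent from catalog) or deprecated.

    Problems are reported, never raised: the report reconciles
    ``retained + excluded_invalid + excluded_deprecated`` with the
    input row count and lists every excluded (code, reason) pair.
    """
    if "code" not in cases.columns:
        raise KeyError("case table must have a 'code' column")
    deprecated_set = {_pad(c) for c in deprecated}
    codes = cases["code"].map(_pad)
    is_deprecated = codes.isin(deprecated_set)
    in_catalog = codes.map(lambda c: c in catalog)
    is_invalid = ~in_catalog & ~is_deprecated
    keep = in_catalog & ~is_deprecated
    excluded = [
        (c, "deprecated") for c in codes[is_deprecated]
    ] + [(c, "invalid") for c in codes[is_invalid]]
    report = CaseFilterReport(
        retained=int(keep.sum()),
        excluded_invalid=int(is_invalid.sum()),
        excluded_deprecated=int(is_deprecated.sum()),
        excluded_codes=excluded,
    )
    return cases.loc[keep].copy(), report
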