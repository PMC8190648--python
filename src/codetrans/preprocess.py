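"""Text curation for short clinical phrases.

Operative procedure texts are short (a handful of tokens), manually
entered, and noisy: inconsistent casing and whitespace, misspellings,
ad-hoc acronyms. The curation pipeline applies, in a fixed order,

    trim -> lowercase -> acronym expansion -> spelling correction
         -> stopword removal -> lemmatization

so that multi-word acronym expansions are themselves spell-corrected
and stopword-filtered. Lexicons (spelling map, acronym map, stopword
list) are user data; small demonstration defaults ship with the
package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "NormalizationLexicons",
    "NormalizedText",
    "ALL_STEPS",
    "tokenize",
    "normalize",
    "build_input",
    "default_stopwords",
    "load_lexicon_tsv",
    "load_stopwords",
]

#: Curation steps in their fixed application order.
ALL_STEPS: tuple[str, ...] = (
    "trim",
    "lowercase",
    "acronym",
    "spell",
    "stopwords",
    "lemmatize",
)

_PUNCT = re.compile(r"[^\w\s]|_")
_WS = re.compile(r"\s+")

# Lemmatizer exception list: words whose suffix looks inflected but is not.
_LEMMA_EXCEPTIONS = {
    "bilateral", "lateral", "distal", "proximal", "renal", "spinal",
    "anesthesia", "arthroplasty", "biopsy", "during", "sling", "imaging",
    "screening", "pancreas", "abscess", "bypass", "diagnosis", "stenosis",
    "pelvis", "this", "previous", "thus", "lens", "axillary", "unilateral",
    "closed", "bed", "red", "need", "blood", "cardiac",
}


def default_stopwords() -> frozenset[str]:
    """Minimal English function-word list shipped with the package."""
    text = resources.files("codetrans.data").joinpath("stopwords.txt").read_text()
    return frozenset(t.strip() for t in text.splitlines() if t.strip())


@dataclass(frozen=True)
class NormalizationLexicons:
    """Spelling, acronym, and stopword resources for curation.

    ``spelling`` maps a misspelled token to its correction (no key may
    map to itself); ``acronyms`` maps an acronym token to a non-empty
    expansion phrase.
    """

    stopwords: frozenset[str] = field(default_factory=frozenset)
    spelling: Mapping[str, str] = field(default_factory=dict)
    acronyms: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.spelling.items():
            if k == v:
                raise ValueError(f"spelling entry maps {k!r} to itself")
        for k, v in self.acronyms.items():
            if not v.strip():
                raise ValueError(f"acronym {k!r} has empty expansion")


@dataclass(frozen=True)
class NormalizedText:
    """Curated text as a token list and its single-space join."""

    tokens: tuple[str, ...]

    @property
    def joined(self) -> str:
        return " ".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(text: str) -> list[str]:
    """Split on whitespace after mapping punctuation to spaces.

    Suited to short phrases, not prose; hyphens and slashes act as
    separators so ``"knee-joint"`` yields two tokens.
    """
    return _WS.sub(" ", _PUNCT.sub(" ", text)).split()


def _lemmatize_token(tok: str) -> str:
    """Rule-based suffix stripper for plurals, -ing and -ed forms,
    iterated to a fixed point so lemmatization is idempotent."""
    for _ in range(5):
        out = _strip_suffix(tok)
        if out == tok:
            return out
        tok = out
    return tok


def _strip_suffix(tok: str) -> str:
    if tok in _LEMMA_EXCEPTIONS or len(tok) <= 3 or not tok.isalpha():
        return tok
    if tok.endswith("ies") and len(tok) > 4:
        return tok[:-3] + "y"
    if tok.endswith("sses"):
        return tok[:-2]
    if tok.endswith("s") and not tok.endswith(("ss", "us", "is")):
        return tok[:-1]
    if tok.endswith("ing") and len(tok) > 5:
        stem = tok[:-3]
        return stem + "e" if _needs_e(stem) else stem
    if tok.endswith("ed") and len(tok) > 4:
        stem = tok[:-2]
        return stem + "e" if _needs_e(stem) else stem
    return tok


def _needs_e(stem: str) -> bool:
    # "imag(ing)" -> "image", "replac(ed)" -> "replace"; crude but
    # adequate for short procedure phrases.
    return len(stem) >= 3 and stem[-1] in "cgsuv" and stem[-2] not in "aeiou"


def normalize(
    text: str,
    lexicons: NormalizationLexicons | None = None,
    steps: Iterable[str] = ALL_STEPS,
) -> NormalizedText:
    """Curate a raw string through the fixed-order pipeline.

    ``steps`` selects a subset of :data:`ALL_STEPS`; application order
    is always the canonical one regardless of the order given. Empty
    input yields an empty :class:`NormalizedText`. Deterministic.
    """
    lex = lexicons or NormalizationLexicons()
    requested = set(steps)
    unknown = requested - set(ALL_STEPS)
    if unknown:
        raise ValueError(f"unknown normalization steps: {sorted(unknown)}")

    if "trim" in requested:
        text = text.strip()
    if "lowercase" in requested:
        text = text.lower()
    tokens = tokenize(text)
    if "acronym" in requested:
        expanded: list[str] = []
        for tok in tokens:
            if tok in lex.acronyms:
                expanded.extend(tokenize(lex.acronyms[tok].lower()))
            else:
                expanded.append(tok)
        tokens = expanded
    if "spell" in requested:
        tokens = [lex.spelling.get(tok, tok) for tok in tokens]
    if "stopwords" in requested:
        tokens = [tok for tok in tokens if tok not in lex.stopwords]
    if "lemmatize" in requested:
        tokens = [_lemmatize_token(tok) for tok in tokens]
    return NormalizedText(tokens=tuple(tokens))


#: Input construction modes for the three experimental settings.
MODES = ("raw", "curated", "curated+diagnosis")


def build_input(
    procedure_text: str,
    preop_diagnosis: str = "",
    mode: str = "curated",
    lexicons: NormalizationLexicons | None = None,
    steps: Iterable[str] = ALL_STEPS,
) -> str:
    """Construct the model source string for one case.

    ``raw`` passes the procedure text through untouched; ``curated``
    normalizes it; ``curated+diagnosis`` appends the normalized
    preoperative diagnosis to the normalized procedure text. A missing
    diagnosis degrades mode 3 to mode 2.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "raw":
        return procedure_text
    src = normalize(procedure_text, lexicons, steps).joined
    if mode == "curated+diagnosis" and preop_diagnosis and preop_diagnosis.strip():
        diag = normalize(preop_diagnosis, lexicons, steps).joined
        if diag:
            src = f"{src} {diag}" if src else diag
    return src


def load_lexicon_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column key<TAB>value lexicon file (no header)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("\t")
        out[key.strip()] = value.strip()
    return out


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a one-token-per-line stopword file."""
    return frozenset(
        t.strip() for t in Path(path).read_text().splitlines() if t.strip()
    )
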