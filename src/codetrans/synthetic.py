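"""Synthetic catalogs and operative-case corpora.

Real operative registries cannot be shipped, so this module generates
data with the same statistical shape: long canonical code descriptions
(mean ~13 tokens), short noisy procedure texts (mean ~5 tokens),
shorter informative preoperative diagnoses (mean ~4 tokens), a
long-tailed Zipf label law (top ~20% of codes carrying ~80% of cases),
and date-stamped records spanning a study window so a calendar cutoff
yields a temporal holdout.

Each case's procedure text starts from a canonical short phrase — a
compressed paraphrase of its code's description that always contains
the code's discriminative core tokens — and is corrupted by recorded
noise operators (acronym substitution, character-level misspelling,
token dropout, adjacent-token reordering). The record of applied
operators makes every emitted text exactly replayable, and observed
corruptions double as demonstration spelling/acronym lexicons for the
curation pipeline.

All randomness flows from one seed through named streams (catalog,
labels, noise, dates, diagnosis), so changing e.g. the noise draw
leaves label assignments untouched.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .catalog import CodeCatalog, CodeEntry
from .corpus import OperativeCase
from .preprocess import NormalizationLexicons

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "make_catalog",
    "acronym_table",
    "simulate_cases",
    "replay_ops",
    "lexicons_from_truth",
    "zipf_weights",
    "PAPERLIKE",
]

# ------------------------------------------------------------ word pools

_REGIONS = [
    "head", "neck", "shoulder", "elbow", "forearm", "wrist", "hand",
    "chest", "lung", "heart", "esophagus", "stomach", "liver", "pancreas",
    "kidney", "bladder", "uterus", "prostate", "hip", "femur", "knee",
    "tibia", "ankle", "foot", "spine", "brain", "eye", "ear", "nose",
    "throat", "colon", "rectum", "breast", "skin", "artery", "vein",
    "nerve", "tendon", "muscle", "bone",
]
_KINDS = [
    "open", "closed", "endoscopic", "arthroscopic", "laparoscopic",
    "percutaneous", "diagnostic", "therapeutic", "reconstructive",
    "radical", "partial", "total", "revision", "emergency", "elective",
]
_PROCEDURES = [
    "repair", "excision", "biopsy", "transplant", "replacement", "fusion",
    "resection", "drainage", "exploration", "reduction", "fixation",
    "amputation", "grafting", "imaging", "decompression", "ligation",
    "bypass", "dilation", "ablation", "reconstruction",
]
_QUALIFIERS = [
    "urinary tract", "lymph nodes", "soft tissue", "vascular structures",
    "joint capsule", "surrounding tissue", "regional nerves",
    "supporting ligaments", "adjacent organs", "deep fascia",
]
_EXTRAS = [
    "with graft harvesting", "with image guidance", "with sedation care",
    "not otherwise specified", "with monitoring devices",
    "with catheter placement", "requiring field avoidance",
    "with pump oxygenator",
]
_CONDITIONS = [
    "fracture", "arthritis", "neoplasm", "stenosis", "infection",
    "obstruction", "hernia", "dislocation", "failure", "hemorrhage",
    "cyst", "calculus", "injury", "degeneration", "tear", "rupture",
]
_SEVERITY = ["acute", "chronic", "recurrent", "severe", "progressive"]
_LATERALITY = ["left", "right", "bilateral"]
_ALPHABET = "abcdefghijklmnopqrstuvwxyz"

_STREAMS = {"catalog": 0, "labels": 1, "noise": 2, "dates": 3, "diagnosis": 4}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name]]))


# ------------------------------------------------------------ config

@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; defaults emulate the registry statistics.

    ``zipf_exponent`` 1.2 puts roughly 80% of case mass on the most
    frequent ~20% of codes. Noise rates are per-token (misspell,
    dropout) or per-case (acronym, reorder) probabilities.
    """

    n_codes: int = 250
    n_cases: int = 20_000
    zipf_exponent: float = 1.2
    misspell_rate: float = 0.1
    acronym_rate: float = 0.1
    token_dropout_rate: float = 0.05
    reorder_rate: float = 0.05
    diagnosis_vocab_per_code: int = 3
    date_range: tuple[dt.date, dt.date] = (dt.date(2017, 1, 1), dt.date(2019, 6, 30))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codes < 2:
            raise ValueError("n_codes must be at least 2")
        if self.n_cases < self.n_codes:
            raise ValueError("n_cases must be at least n_codes")
        for name in ("misspell_rate", "acronym_rate", "token_dropout_rate",
                     "reorder_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")

    def noiseless(self) -> "SynthConfig":
        """Copy with every noise operator switched off."""
        return replace(self, misspell_rate=0.0, acronym_rate=0.0,
                       token_dropout_rate=0.0, reorder_rate=0.0)


#: Desk-scale preset mirroring the registry's shape.
PAPERLIKE = SynthConfig()


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth for one emitted case: the canonical short phrase,
    the noise operators applied to it, and the gold code."""

    case_id: str
    code: str
    canonical_phrase: tuple[str, ...]
    ops: tuple[dict, ...]


# ------------------------------------------------------------ catalog

def _core_triple(rng: np.random.Generator, used: set) -> tuple[str, str, str]:
    while True:
        triple = (
            _KINDS[rng.integers(len(_KINDS))],
            _PROCEDURES[rng.integers(len(_PROCEDURES))],
            _REGIONS[rng.integers(len(_REGIONS))],
        )
        if triple not in used:
            used.add(triple)
            return triple


def make_catalog(n_codes: int, seed: int = 0) -> CodeCatalog:
    """Generate a catalog of distinct long canonical descriptions.

    Codes are zero-padded sequential identifiers grouped into synthetic
    body-region ranges. Each description is built around a unique
    (kind, procedure, region) core triple — e.g. "anesthesia for open
    repair procedures on knee" — extended with qualifier and extra
    phrases to a mean length near 13 tokens.
    """
    if n_codes < 2:
        raise ValueError("n_codes must be at least 2")
    rng = _stream(seed, "catalog")
    used: set = set()
    entries: list[CodeEntry] = []
    triples: list[tuple[str, str, str]] = []
    for i in range(n_codes):
        kind, proc, region = _core_triple(rng, used)
        triples.append((kind, proc, region))
        tokens = ["anesthesia", "for", kind, proc, "procedures", "on", region]
        # extend toward a target length drawn around 13 tokens
        target = int(np.clip(round(rng.normal(13.0, 3.0)), 8, 20))
        if len(tokens) < target:
            qual = _QUALIFIERS[rng.integers(len(_QUALIFIERS))].split()
            tokens += ["including"] + qual
        if len(tokens) < target:
            tokens += ["and"] + _QUALIFIERS[rng.integers(len(_QUALIFIERS))].split()
        if len(tokens) < target:
            tokens += _EXTRAS[rng.integers(len(_EXTRAS))].split()
        code = f"{100 + i * 4:05d}"
        entries.append(CodeEntry(code=code, preferred_term=" ".join(tokens)))
    # contiguous synthetic body-region ranges, ~5 categories
    n_cat = max(2, min(5, n_codes // 10)) if n_codes >= 20 else 2
    bounds = np.array_split(np.arange(n_codes), n_cat)
    ranges = {}
    cat_names = [f"region group {chr(ord('A') + i)}" for i in range(n_cat)]
    labelled = []
    for name, idx in zip(cat_names, bounds):
        if len(idx) == 0:
            continue
        ranges[name] = (entries[idx[0]].code, entries[idx[-1]].code)
        for j in idx:
            labelled.append(CodeEntry(code=entries[j].code,
                                      preferred_term=entries[j].preferred_term,
                                      category=name))
    return CodeCatalog(entries=labelled, category_ranges=ranges)


def acronym_table(catalog: CodeCatalog) -> dict[str, str]:
    """Acronym -> expansion lexicon derived from catalog descriptions.

    For each description the (kind, procedure) bigram after
    "anesthesia for" becomes an acronym of its initials (e.g. "total
    replacement" -> "tr"); colliding acronyms keep their first
    expansion only, and acronyms that shadow a real vocabulary word are
    skipped.
    """
    vocab = set(_REGIONS) | set(_KINDS) | set(_PROCEDURES)
    table: dict[str, str] = {}
    for term in catalog.terms:
        toks = term.split()
        if len(toks) < 4 or toks[:2] != ["anesthesia", "for"]:
            continue
        expansion = f"{toks[2]} {toks[3]}"
        acr = toks[2][0] + toks[3][0]
        if acr in vocab:
            continue
        table.setdefault(acr, expansion)
    return table


# ------------------------------------------------------------ noise ops

def _apply_op(tokens: list[str], op: dict) -> list[str]:
    kind = op["op"]
    if kind == "replace_span":
        i, n = op["i"], op["n"]
        return tokens[:i] + [op["token"]] + tokens[i + n:]
    if kind == "misspell":
        out = list(tokens)
        out[op["i"]] = op["token"]
        return out
    if kind == "dropout":
        return tokens[: op["i"]] + tokens[op["i"] + 1:]
    if kind == "reorder":
        out = list(tokens)
        i = op["i"]
        out[i], out[i + 1] = out[i + 1], out[i]
        return out
    raise ValueError(f"unknown noise operator {kind!r}")


def replay_ops(canonical: Sequence[str], ops: Sequence[dict]) -> str:
    """Re-apply a recorded operator sequence to the canonical phrase;
    reproduces the emitted procedure text exactly."""
    tokens = list(canonical)
    for op in ops:
        tokens = _apply_op(tokens, op)
    return " ".join(tokens)


def _misspell(token: str, rng: np.random.Generator) -> str:
    """One random character edit (insert, delete, or substitute)."""
    choice = rng.integers(3)
    pos = int(rng.integers(len(token) + (1 if choice == 0 else 0)))
    ch = _ALPHABET[rng.integers(26)]
    if choice == 0:
        return token[:pos] + ch + token[pos:]
    if choice == 1 and len(token) > 1:
        return token[:pos] + token[pos + 1:]
    new = token[:pos] + ch + token[pos + 1:]
    return new if new != token else (token + ch)


# ------------------------------------------------------------ cases

def zipf_weights(n: int, exponent: float) -> np.ndarray:
    """Truncated Zipf probability vector over ranks 1..n."""
    w = np.arange(1, n + 1, dtype=float) ** -exponent
    return w / w.sum()


def _short_phrase(term_tokens: list[str], rng: np.random.Generator) -> list[str]:
    """Canonical short phrase: the core triple plus optional extra
    content tokens from the description, in description order, with an
    optional laterality prefix."""
    kind, proc, region = term_tokens[2], term_tokens[3], term_tokens[6]
    core_idx = [2, 3, 6]
    extra_pool = [i for i in range(7, len(term_tokens))
                  if term_tokens[i] not in ("including", "and", "with", "not",
                                            "on", "for", "of")]
    target = int(np.clip(round(rng.normal(5.0, 1.3)), 3, 7))
    n_extra = min(max(target - 3, 0), len(extra_pool))
    chosen = sorted(core_idx + [int(extra_pool[j]) for j in
                    rng.choice(len(extra_pool), size=n_extra, replace=False)]
                    ) if n_extra else core_idx
    phrase = [term_tokens[i] for i in chosen]
    if rng.random() < 0.4:
        phrase = [_LATERALITY[rng.integers(3)]] + phrase
    return phrase


def _diagnosis_vocab(region: str, code_index: int, n_phrases: int,
                     rng: np.random.Generator) -> list[str]:
    """Per-code diagnosis phrases: region + code-specific conditions."""
    out = []
    for j in range(n_phrases):
        cond = _CONDITIONS[(code_index * n_phrases + j) % len(_CONDITIONS)]
        toks = [region, cond]
        if rng.random() < 0.6:
            toks = [_SEVERITY[rng.integers(len(_SEVERITY))]] + toks
        if rng.random() < 0.3:
            toks += ["requiring", "intervention"]
        out.append(" ".join(toks))
    return out


def simulate_cases(
    catalog: CodeCatalog, config: SynthConfig
) -> tuple[list[OperativeCase], list[SynthTruth]]:
    """Draw a corpus of operative cases from the catalog.

    Codes follow a truncated Zipf law in catalog order (catalog index =
    designed frequency rank). Each case's procedure text is its code's
    canonical short phrase corrupted by the configured noise operators;
    the preoperative diagnosis is drawn from the code's own diagnosis
    vocabulary (informative about the code); dates are uniform over the
    date range. Byte-identical output for a given catalog, config, and
    seed.
    """
    if config.n_codes != len(catalog):
        config = replace(config, n_codes=len(catalog))
    n = len(catalog)
    rng_labels = _stream(config.seed, "labels")
    rng_noise = _stream(config.seed, "noise")
    rng_dates = _stream(config.seed, "dates")
    rng_diag = _stream(config.seed, "diagnosis")

    weights = zipf_weights(n, config.zipf_exponent)
    code_idx = rng_labels.choice(n, size=config.n_cases, p=weights)

    term_tokens = [t.split() for t in catalog.terms]
    acr_by_expansion = {v: k for k, v in acronym_table(catalog).items()}
    diag_vocab = [
        _diagnosis_vocab(term_tokens[i][6], i, config.diagnosis_vocab_per_code,
                         rng_diag)
        for i in range(n)
    ]

    start, end = config.date_range
    n_days = (end - start).days
    if n_days < 0:
        raise ValueError("date_range end precedes start")
    day_offsets = rng_dates.integers(0, n_days + 1, size=config.n_cases)

    cases: list[OperativeCase] = []
    truths: list[SynthTruth] = []
    for m in range(config.n_cases):
        ci = int(code_idx[m])
        toks = term_tokens[ci]
        phrase = _short_phrase(toks, rng_noise)
        canonical = tuple(phrase)
        ops: list[dict] = []
        tokens = list(phrase)

        # acronym substitution of the adjacent (kind, procedure) span
        expansion = f"{toks[2]} {toks[3]}"
        if expansion in acr_by_expansion and rng_noise.random() < config.acronym_rate:
            for i in range(len(tokens) - 1):
                if tokens[i] == toks[2] and tokens[i + 1] == toks[3]:
                    op = {"op": "replace_span", "i": i, "n": 2,
                          "token": acr_by_expansion[expansion]}
                    ops.append(op)
                    tokens = _apply_op(tokens, op)
                    break
        # per-token misspellings
        for i in range(len(tokens)):
            if rng_noise.random() < config.misspell_rate:
                op = {"op": "misspell", "i": i,
                      "token": _misspell(tokens[i], rng_noise)}
                ops.append(op)
                tokens = _apply_op(tokens, op)
        # token dropout, keeping at least one token
        i = 0
        while i < len(tokens):
            if len(tokens) > 1 and rng_noise.random() < config.token_dropout_rate:
                op = {"op": "dropout", "i": i}
                ops.append(op)
                tokens = _apply_op(tokens, op)
            else:
                i += 1
        # adjacent-pair reorder
        if len(tokens) > 1 and rng_noise.random() < config.reorder_rate:
            op = {"op": "reorder", "i": int(rng_noise.integers(len(tokens) - 1))}
            ops.append(op)
            tokens = _apply_op(tokens, op)

        case_id = f"case-{m:06d}"
        diag = diag_vocab[ci][int(rng_diag.integers(len(diag_vocab[ci])))]
        cases.append(OperativeCase(
            case_id=case_id,
            date=start + dt.timedelta(days=int(day_offsets[m])),
            procedure_text=" ".join(tokens),
            preop_diagnosis=diag,
            code=catalog.codes[ci],
        ))
        truths.append(SynthTruth(case_id=case_id, code=catalog.codes[ci],
                                 canonical_phrase=canonical, ops=tuple(ops)))
    return cases, truths


def lexicons_from_truth(
    truths: Sequence[SynthTruth],
    catalog: CodeCatalog,
    stopwords: frozenset[str] = frozenset(),
) -> NormalizationLexicons:
    """Demonstration curation lexicons recovered from generation truth.

    Misspell operators yield a corrupted -> original spelling map
    (colliding or identity entries dropped); the acronym table comes
    from the catalog. Emulates a manually reviewed lexicon at desk
    scale.
    """
    spelling: dict[str, str] = {}
    dropped: set[str] = set()
    for t in truths:
        tokens = list(t.canonical_phrase)
        for op in t.ops:
            if op["op"] == "misspell":
                orig, bad = tokens[op["i"]], op["token"]
                if bad != orig:
                    if bad in spelling and spelling[bad] != orig:
                        dropped.add(bad)
                    else:
                        spelling.setdefault(bad, orig)
            tokens = _apply_op(tokens, op)
    for bad in dropped:
        spelling.pop(bad, None)
    return NormalizationLexicons(
        stopwords=stopwords,
        spelling=spelling,
        acronyms=dict(acronym_table(catalog)),
    )
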