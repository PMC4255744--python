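"""Text normalization, sentence splitting, verb and quantity spotting.

Protocol prose is written in a restricted imperative register ("Incubate at
30°C overnight."), which makes reliable rule-based processing possible
without a statistical part-of-speech tagger: candidate action verbs sit in
imperative position (sentence-initial) or immediately after a coordinator
("and", "then", ","), and descriptor values announce themselves through
semantic clues — a number next to "°C" is a temperature, next to "min" a
period, and so on.  An external tagger can be plugged in upstream by
pre-splitting text, but the default path has no model dependency.

All offsets are 0-based half-open character spans into the normalized
document.  Every operation here is deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .units import UnitTable, load_unit_table

__all__ = [
    "Sentence",
    "QuantityMention",
    "normalize_text",
    "split_sentences",
    "find_candidate_verbs",
    "find_quantities",
    "lemma_variants",
]


@dataclass(frozen=True)
class Sentence:
    index: int
    text: str
    char_span: tuple[int, int]  # half-open, into the normalized document


@dataclass(frozen=True)
class QuantityMention:
    magnitude: float
    unit_symbol: str  # canonical symbol from the unit table
    unit_id: str | None  # Units Ontology accession, if the table has one
    char_span: tuple[int, int]  # half-open, document offsets
    kind_hint: str | None  # descriptor kind the unit signals


# tokens that may legitimately precede a sentence-internal period
_NONBREAKING = {"e.g", "i.e", "fig", "figs", "al", "vs", "no", "approx", "ca", "cf", "etc"}

_WS_RE = re.compile(r"[ \t]+")


def normalize_text(raw: str | bytes) -> str:
    """Unify line endings, fold unicode variants, collapse whitespace.

    ``°C`` written with intervening space ("30 °C", "30 ° C") is folded to
    the attached canonical form; the micro-sign variant µ (U+00B5) becomes
    Greek μ (U+03BC).  Idempotent.
    """
    if isinstance(raw, bytes):
        raw = raw.decode("utf-8")  # UnicodeDecodeError on non-text bytes
    text = raw.replace("\r\n", "\n").replace("\r", "\n")
    text = text.replace("℃", "°C").replace("℉", "°F")
    text = text.replace("µ", "μ")
    text = re.sub(r"[ \t]*°[ \t]*C\b", "°C", text)
    text = re.sub(r"[ \t]*°[ \t]*F\b", "°F", text)
    text = _WS_RE.sub(" ", text)
    text = re.sub(r" ?\n ?", "\n", text)
    text = re.sub(r"\n+", "\n", text)
    return text.strip()


def split_sentences(doc: str) -> list[Sentence]:
    """Split normalized text into sentences.

    Boundaries are ``.``/``!``/``?`` followed by whitespace or end of text,
    and newlines.  A period after a known non-breaking abbreviation
    ("e.g.", "Fig.") or inside a decimal number is not a boundary.
    """
    boundaries: list[int] = []  # end offset (exclusive) of each sentence
    for m in re.finditer(r"[.!?]+(?=\s|$)|\n", doc):
        if m.group().startswith("."):
            before = doc[: m.start()]
            tok = re.search(r"([A-Za-z][\w.]*)$", before)
            if tok and tok.group(1).lower().rstrip(".") in _NONBREAKING:
                continue
        boundaries.append(m.end())
    boundaries.append(len(doc))

    sentences: list[Sentence] = []
    start = 0
    for end in boundaries:
        seg = doc[start:end]
        lstrip = len(seg) - len(seg.lstrip())
        rstrip = len(seg) - len(seg.rstrip())
        s, e = start + lstrip, end - rstrip
        if e > s:
            sentences.append(Sentence(len(sentences), doc[s:e], (s, e)))
        start = end
    return sentences


def lemma_variants(token: str) -> list[str]:
    """Candidate lemmas for a (possibly inflected) verb token.

    Strips regular inflections -s/-ed/-ing with standard consonant
    un-doubling and e-restoration; the raw lowercase form comes first, so
    an uninflected imperative always matches directly.
    """
    t = token.lower()
    variants = [t]

    def _expand(stem: str) -> list[str]:
        out = [stem]
        if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in "aeiou":
            out.append(stem[:-1])  # stirr -> stir
        if stem and stem[-1] not in "aeiou":
            out.append(stem + "e")  # incubat -> incubate
        return out

    if t.endswith("ing") and len(t) > 4:
        variants += _expand(t[:-3])
    if t.endswith("ied") and len(t) > 4:
        variants.append(t[:-3] + "y")  # dried -> dry
    elif t.endswith("ed") and len(t) > 3:
        variants += _expand(t[:-2])
        variants.append(t[:-1])  # stored -> store
    if t.endswith("ies") and len(t) > 4:
        variants.append(t[:-3] + "y")
    elif t.endswith("es") and len(t) > 3:
        variants.append(t[:-2])
        variants.append(t[:-1])
    elif t.endswith("s") and len(t) > 2:
        variants.append(t[:-1])
    seen: set[str] = set()
    return [v for v in variants if not (v in seen or seen.add(v))]


# adverbs/ordinals that may precede the imperative verb
_LEADING_SKIP = {
    "then", "next", "first", "second", "third", "finally", "now", "carefully",
    "gently", "immediately", "afterwards", "subsequently", "briefly",
    "quickly", "slowly", "always",
}
_COORDINATORS = {"and", "then"}

_WORD_RE = re.compile(r"[A-Za-z][A-Za-z\-']*")


def find_candidate_verbs(
    sentence: Sentence, lexicon: frozenset[str] | set[str] | None = None
) -> list[tuple[str, tuple[int, int]]]:
    """Candidate action-verb lemmas with document spans.

    Candidates are the first content token (imperative position, skipping a
    small set of leading adverbs) and tokens following a coordinator
    ("and", "then", or a comma).  When a ``lexicon`` is given, each token's
    inflection variants are checked against it and the matching lemma is
    returned; coordinated tokens with no lexicon hit are dropped, while the
    imperative-position token is always reported (its failure to match
    downstream marks the sentence as unmatched).
    """
    base = sentence.char_span[0]
    tokens = list(_WORD_RE.finditer(sentence.text))
    out: list[tuple[str, tuple[int, int]]] = []
    first_seen = False
    for i, m in enumerate(tokens):
        word = m.group()
        positional = False
        if not first_seen:
            if word.lower() in _LEADING_SKIP:
                continue
            first_seen = True
            positional = True
        coordinated = False
        if not positional and i > 0:
            prev = tokens[i - 1]
            gap = sentence.text[prev.end():m.start()]
            if prev.group().lower() in _COORDINATORS or "," in gap:
                coordinated = True
        if not (positional or coordinated):
            continue
        variants = lemma_variants(word)
        span = (base + m.start(), base + m.end())
        if lexicon is not None:
            hit = next((v for v in variants if v in lexicon), None)
            if hit is not None:
                out.append((hit, span))
            elif positional:
                out.append((variants[0], span))
        else:
            out.append((variants[0], span))
    return out


def find_quantities(sentence: Sentence, units: UnitTable | None = None) -> list[QuantityMention]:
    """All number-unit pairs in a sentence, with descriptor-kind hints.

    Mentions never overlap; compound units (μg/mL) win over their prefixes
    (μg) because the unit alternation is ordered longest-first.
    """
    units = units or load_unit_table()
    base = sentence.char_span[0]
    mentions: list[QuantityMention] = []
    for m in units.quantity_pattern().finditer(sentence.text):
        info = units.resolve(m.group(2))
        assert info is not None
        mentions.append(
            QuantityMention(
                magnitude=float(m.group(1)),
                unit_symbol=info.symbol,
                unit_id=info.uo_id,
                char_span=(base + m.start(), base + m.end()),
                kind_hint=info.kind,
            )
        )
    return mentions
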