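"""Canonicalization of Lao-script and transliterated demographic text.

Equality and string-similarity comparisons are only meaningful after the
free-text fields have been canonicalized: Unicode NFC, whitespace removal
(Lao is written without spaces; transliterations vary), upper-casing of
Latin letters, and an ordered substitution table (:class:`CharMap`) that
rewrites ligatures, Lao digits and other variant code points to a single
standard form.  An optional *phonetic-merge* layer additionally collapses
the confusable short/long vowel pair and strips tone marks, so that tonal
spelling variants of the same name (e.g. the two spellings of "Souksan")
compare equal.
"""

from __future__ import annotations

import csv
import logging
import re
import unicodedata
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .records import TEXT_COLUMNS, is_missing as _is_missing

logger = logging.getLogger("laolink")

_WHITESPACE = re.compile(r"\s+")

#: Names recorded before a Lao child receives a permanent name, plus honorific
#: stand-ins; stored in canonical form.
DEFAULT_PLACEHOLDERS = ("EANOI", "ແອນ້ອຍ", "MR.", "MR", "MISS")

_SEX_MAP = {
    "M": "male", "MALE": "male", "ຊາຍ": "male", "1": "male",
    "F": "female", "FEMALE": "female", "ຍິງ": "female", "2": "female",
}

#: Lao mobile/landline numbers: optional +856 country code or leading 0,
#: then 6-12 digits.
_PHONE = re.compile(r"^(?:\+?856|0)\d{6,12}$")


class CharMapError(ValueError):
    """A substitution table is cyclic or not idempotent."""


class CharMap:
    """Ordered grapheme substitution table.

    Rules are applied once each, in order.  The table must be idempotent:
    applying it a second time changes nothing.  This is checked at load time
    (it also rules out rewrite cycles).
    """

    def __init__(self, rules: Sequence[tuple[str, str]]):
        self.rules = [(unicodedata.normalize("NFC", s), unicodedata.normalize("NFC", t))
                      for s, t in rules]
        self._validate()

    def _validate(self) -> None:
        for src, tgt in self.rules:
            if not src:
                raise CharMapError("empty source grapheme")
            once = self.apply(tgt)
            if once != tgt:
                raise CharMapError(
                    f"rule {src!r} -> {tgt!r} is not idempotent: target rewrites to {once!r}"
                )

    def apply(self, s: str) -> str:
        for src, tgt in self.rules:
            s = s.replace(src, tgt)
        return s

    @classmethod
    def from_csv(cls, path) -> "CharMap":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            rules = [(row["source"], row["target"]) for row in reader]
        return cls(rules)

    @classmethod
    def default(cls) -> "CharMap":
        """Ligature, digit-form and vowel-sign standardization."""
        return cls._bundled("charmap_default.csv")

    @classmethod
    def phonetic(cls) -> "CharMap":
        """Confusable-vowel merge and tone-mark stripping."""
        return cls._bundled("charmap_phonetic.csv")

    @classmethod
    def _bundled(cls, name: str) -> "CharMap":
        ref = resources.files("laolink.data") / name
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


def normalize_text(
    s,
    charmap: CharMap | None = None,
    *,
    phonetic: CharMap | None = None,
):
    """Canonicalize one free-text value; missing in, missing out.

    NFC first (Lao combining marks admit several byte orders), then control
    characters are stripped, all whitespace removed, Latin letters
    upper-cased, and the substitution table(s) applied.  Total and
    idempotent.
    """
    if _is_missing(s):
        return None
    s = unicodedata.normalize("NFC", str(s))
    cleaned = "".join(ch for ch in s if unicodedata.category(ch) not in ("Cc", "Cf"))
    if len(cleaned) != len(s):
        logger.debug("normalize_text: stripped %d control characters", len(s) - len(cleaned))
    s = _WHITESPACE.sub("", cleaned)
    s = s.upper()
    if charmap is not None:
        s = charmap.apply(s)
    if phonetic is not None:
        s = phonetic.apply(s)
    s = unicodedata.normalize("NFC", s)
    return s if s else None


def normalize_sex(value) -> object:
    """Map a raw sex value onto {male, female, unknown}; missing stays missing."""
    if _is_missing(value):
        return None
    v = str(value).strip().upper()
    return _SEX_MAP.get(v, "unknown")


def normalize_contact(value) -> tuple[object, bool]:
    """Canonicalize a phone string; returns (canonical, invalid_flag).

    Separator characters are dropped before checking the Lao phone format.
    A failing value is flagged, not discarded.
    """
    if _is_missing(value):
        return None, False
    v = re.sub(r"[\s\-().]", "", str(value))
    return v, not bool(_PHONE.match(v))


def placeholder_flag(name, placeholders: Iterable[str] = DEFAULT_PLACEHOLDERS) -> bool:
    """True iff a canonical name is a configured placeholder (e.g. "Eanoi").

    Missing names are not placeholders; missingness is handled separately.
    """
    if _is_missing(name):
        return False
    return name in set(placeholders)


def normalize_records(
    df: pd.DataFrame,
    charmap: CharMap | None = None,
    *,
    phonetic_merge: bool = False,
    placeholder_as_missing: bool = False,
    placeholders: Iterable[str] = DEFAULT_PLACEHOLDERS,
) -> pd.DataFrame:
    """Normalize every text field of a registry frame.

    Adds ``placeholder_name`` (bool) and ``contact_invalid`` (bool) columns.
    With ``placeholder_as_missing`` the configured placeholder names are
    demoted to missing so that downstream comparisons treat them as "not
    available" rather than as agreeing values.  The default leaves them in
    place: placeholders then compare as ordinary values, which is the
    behaviour observed in practice (temporary names are a known source of
    spurious agreement).
    """
    if charmap is None:
        charmap = CharMap.default()
    phon = CharMap.phonetic() if phonetic_merge else None
    out = df.copy()
    for col in TEXT_COLUMNS:
        out[col] = [normalize_text(v, charmap, phonetic=phon) for v in out[col]]
    out["sex"] = [normalize_sex(v) for v in out["sex"]]
    contact = [normalize_contact(v) for v in out["contact"]]
    out["contact"] = [c for c, _ in contact]
    out["contact_invalid"] = [bad for _, bad in contact]
    canon_placeholders = {normalize_text(p, charmap, phonetic=phon) for p in placeholders}
    out["placeholder_name"] = [
        placeholder_flag(v, canon_placeholders) for v in out["name"]
    ]
    if placeholder_as_missing:
        out.loc[out["placeholder_name"], "name"] = None
    n_bad = int(out["contact_invalid"].sum())
    if n_bad:
        logger.info("normalize_records: %d contacts fail the Lao phone format", n_bad)
    return out


class LaoNameNormalizer(TransformerMixin, BaseEstimator):
    """Transformer canonicalizing a raw registry frame.

    Stateless (``fit`` only validates); ``transform`` returns the normalized
    frame with the same rows.

    Parameters
    ----------
    charmap_path : str or None
        CSV override for the substitution table; ``None`` uses the bundled
        default.
    phonetic_merge : bool
        Also collapse confusable vowels and tone marks.
    placeholder_as_missing : bool
        Treat placeholder names ("Eanoi", honorifics) as missing.
    """

    def __init__(self, charmap_path=None, phonetic_merge=False,
                 placeholder_as_missing=False,
                 placeholders=DEFAULT_PLACEHOLDERS):
        self.charmap_path = charmap_path
        self.phonetic_merge = phonetic_merge
        self.placeholder_as_missing = placeholder_as_missing
        self.placeholders = placeholders

    def fit(self, X: pd.DataFrame, y=None):
        missing = [c for c in TEXT_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"input frame lacks text columns: {missing}")
        self.charmap_ = (
            CharMap.from_csv(self.charmap_path)
            if self.charmap_path is not None
            else CharMap.default()
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "charmap_"):
            self.fit(X)
        return normalize_records(
            X,
            self.charmap_,
            phonetic_merge=self.phonetic_merge,
            placeholder_as_missing=self.placeholder_as_missing,
            placeholders=self.placeholders,
        )
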