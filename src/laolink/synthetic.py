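"""Synthetic Lao-like child health registries with known truth partitions.

The generator emulates the statistical structure a registry deduplication
study has to cope with: a configurable fraction of records belonging to
duplicate clusters of sizes 2-5, realistic field incompleteness (family
names and contact numbers largely absent), placeholder names recorded
before a child is permanently named ("Eanoi" and honorific stand-ins),
twins who share DOB, village and parents while being distinct children,
and Lao-specific spelling noise (tonal-mark and confusable-vowel swaps,
transliteration variants, character transpositions).  Every draw flows
from one seed, so a configuration reproduces byte-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .records import RAW_COLUMNS, Partition
from .deterministic import (
    DEFAULT_BLOCK_KEYS,
    NAME_FIELDS,
    RuleTable,
    block_records,
    field_state,
)
from . import _namepools

_LAO_LO = 0x0E80
_LAO_HI = 0x0EFF

#: Tone marks and the short/long "u" vowel pair used by the corruption
#: operators for Lao-script names.
_TONE_MARKS = ["່", "້", "໊", "໋"]
_VOWEL_PAIR = ("ຸ", "ູ")

#: Transliteration variants observed between romanization conventions.
_TRANSLIT_VARIANTS = [
    ("ph", "p"), ("th", "t"), ("kh", "k"), ("ou", "u"),
    ("x", "s"), ("v", "w"), ("aa", "a"),
]

PLACEHOLDER_EANOI = "ແອນ້ອຍ"


@dataclass(frozen=True)
class CorruptionRates:
    """Per-duplicate-record probabilities of each corruption."""

    name_typo: float = 0.40
    parent_typo: float = 0.20
    dob_error: float = 0.02
    village_error: float = 0.01
    temp_name: float = 0.0  # handled globally via placeholder_rates by default


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic registry.

    Defaults reproduce the marginals of the registry the pipeline targets:
    15.62% of records in duplicate clusters, cluster sizes 2-5 in shares
    0.869/0.114/0.014/0.003, family-name completeness 32%, contact 13%,
    and a ~2.4% placeholder-name rate plus rarer honorific stand-ins.
    """

    n_records: int = 20433
    duplicated_fraction: float = 0.1562
    cluster_size_dist: tuple = ((2, 0.869), (3, 0.114), (4, 0.014), (5, 0.003))
    completeness: tuple = (
        ("name", 1.0), ("family_name", 0.32), ("dob", 1.0), ("sex", 1.0),
        ("village", 1.0), ("father_name", 1.0), ("mother_name", 1.0),
        ("contact", 0.13),
    )
    placeholder_rates: tuple = (
        (PLACEHOLDER_EANOI, 0.024), ("Mr.", 110 / 20433), ("Miss", 80 / 20433),
    )
    twin_rate: float = 0.02
    corruption: CorruptionRates = field(default_factory=CorruptionRates)
    lao_script_fraction: float = 0.3
    n_villages: int = 100
    dob_start: str = "2019-01-01"
    dob_days: int = 1095
    seed: int = 0

    def __post_init__(self):
        rates = [self.duplicated_fraction, self.twin_rate, self.lao_script_fraction]
        rates += [p for _, p in self.placeholder_rates]
        rates += [p for _, p in self.completeness]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        probs = [p for _, p in self.cluster_size_dist]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("cluster-size distribution must sum to 1")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.duplicated_fraction > 0 and self.n_records * self.duplicated_fraction < 2 \
                and round(self.n_records * self.duplicated_fraction) > 0:
            raise ValueError("infeasible config: duplicated fraction yields <2 records")


@dataclass
class TruthPartition:
    """Ground-truth entities plus per-cluster annotations."""

    partition: Partition
    annotations: dict  # cluster label -> {"ordinary", "twin", "temporary-name"}


def _is_lao(s: str) -> bool:
    return any(_LAO_LO <= ord(ch) <= _LAO_HI for ch in s)


def _transpose(s: str, rng: np.random.Generator) -> str:
    if len(s) < 2:
        return s
    i = int(rng.integers(0, len(s) - 1))
    return s[:i] + s[i + 1] + s[i] + s[i + 2:]


def _swap_confusable_vowel(name: str) -> str:
    a, b = _VOWEL_PAIR
    return name.replace(a, "\0").replace(b, a).replace("\0", b)


def _toggle_tone_mark(name: str, rng: np.random.Generator) -> str:
    present = [t for t in _TONE_MARKS if t in name]
    if present:  # drop one tone mark
        t = present[int(rng.integers(0, len(present)))]
        return name.replace(t, "", 1)
    t = _TONE_MARKS[int(rng.integers(0, len(_TONE_MARKS)))]
    i = int(rng.integers(1, max(2, len(name))))
    return name[:i] + t + name[i:]


def _translit_variant(name: str, rng: np.random.Generator) -> str:
    low = name.lower()
    applicable = [(a, b) for a, b in _TRANSLIT_VARIANTS if a in low]
    if not applicable:
        return _transpose(name, rng)
    a, b = applicable[int(rng.integers(0, len(applicable)))]
    i = low.index(a)
    return name[:i] + b + name[i + len(a):]


def corrupt_name(name: str, rng: np.random.Generator, rate: float = 1.0,
                 temp_name_rate: float = 0.0, operator: str | None = None) -> str:
    """Spelling-noise operator for a non-missing name.

    With probability ``temp_name_rate`` the name is replaced outright by the
    placeholder (the record made before the child was permanently named; the
    truth link is the caller's to keep); otherwise, with probability
    ``rate``, one spelling operator is applied — for Lao script a
    confusable-vowel swap, tone-mark toggle, or adjacent transposition; for
    Latin transliterations a romanization-variant substitution or
    transposition.  Zero rates return the name unchanged.  ``operator``
    forces a specific operator ("vowel", "tone", "transpose", "translit",
    "temp") regardless of rates.
    """
    if operator is not None:
        if operator == "temp":
            return PLACEHOLDER_EANOI
        if operator == "vowel":
            return _swap_confusable_vowel(name)
        if operator == "tone":
            return _toggle_tone_mark(name, rng)
        if operator == "transpose":
            return _transpose(name, rng)
        if operator == "translit":
            return _translit_variant(name, rng)
        raise ValueError(f"unknown operator {operator!r}")
    if temp_name_rate > 0 and rng.random() < temp_name_rate:
        return PLACEHOLDER_EANOI
    if rate <= 0 or (rate < 1.0 and rng.random() >= rate):
        return name
    if _is_lao(name):
        choice = rng.integers(0, 3)
        if choice == 0 and (_VOWEL_PAIR[0] in name or _VOWEL_PAIR[1] in name):
            return _swap_confusable_vowel(name)
        if choice == 1:
            return _toggle_tone_mark(name, rng)
        return _transpose(name, rng)
    if rng.random() < 0.7:
        return _translit_variant(name, rng)
    return _transpose(name, rng)


def _sample_sizes(target: int, dist: Sequence[tuple], rng: np.random.Generator) -> list:
    """Draw multi-record cluster sizes until they cover ``target`` records."""
    sizes = []
    values = np.array([s for s, _ in dist])
    probs = np.array([p for _, p in dist], dtype=float)
    probs /= probs.sum()
    remaining = target
    while remaining >= 2:
        s = int(rng.choice(values, p=probs))
        s = min(s, remaining)
        if remaining - s == 1:
            s = s + 1 if s < int(values.max()) else s - 1
        if s < 2:
            break
        sizes.append(s)
        remaining -= s
    return sizes


def _base_person(rng: np.random.Generator, cfg: GeneratorConfig, villages: list) -> dict:
    if rng.random() < cfg.lao_script_fraction:
        name = _namepools.GIVEN_NAMES_LAO[int(rng.integers(0, len(_namepools.GIVEN_NAMES_LAO)))]
    else:
        name = _namepools.GIVEN_NAMES_LATIN[int(rng.integers(0, len(_namepools.GIVEN_NAMES_LATIN)))]
    dob = pd.Timestamp(cfg.dob_start) + pd.Timedelta(days=int(rng.integers(0, cfg.dob_days)))
    return {
        "name": name,
        "family_name": _namepools.FAMILY_NAMES[int(rng.integers(0, len(_namepools.FAMILY_NAMES)))],
        "dob": dob.strftime("%d/%m/%Y"),
        "sex": "M" if rng.random() < 0.5 else "F",
        "village": villages[int(rng.integers(0, len(villages)))],
        "father_name": _namepools.GIVEN_NAMES_LATIN[int(rng.integers(0, len(_namepools.GIVEN_NAMES_LATIN)))],
        "mother_name": _namepools.GIVEN_NAMES_LATIN[int(rng.integers(0, len(_namepools.GIVEN_NAMES_LATIN)))],
        "contact": "020" + "".join(str(int(d)) for d in rng.integers(0, 10, size=8)),
    }


def _duplicate_of(base: dict, rng: np.random.Generator, ops: CorruptionRates,
                  cfg: GeneratorConfig, villages: list) -> dict:
    rec = dict(base)
    if rng.random() < ops.name_typo:
        rec["name"] = corrupt_name(rec["name"], rng, temp_name_rate=ops.temp_name)
    for f in ("father_name", "mother_name"):
        if rng.random() < ops.parent_typo:
            rec[f] = corrupt_name(rec[f], rng)
    if rng.random() < ops.dob_error:
        dob = pd.to_datetime(rec["dob"], format="%d/%m/%Y")
        dob += pd.Timedelta(days=int(rng.integers(1, 31)) * (1 if rng.random() < 0.5 else -1))
        rec["dob"] = dob.strftime("%d/%m/%Y")
    if rng.random() < ops.village_error:
        rec["village"] = villages[int(rng.integers(0, len(villages)))]
    return rec


def generate_registry(config: GeneratorConfig | None = None,
                      seed: int | None = None) -> tuple:
    """Generate (records frame, TruthPartition); deterministic given seed."""
    cfg = config if config is not None else GeneratorConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    villages = _namepools.VILLAGES[: cfg.n_villages]

    target_dup = round(cfg.n_records * cfg.duplicated_fraction)
    sizes = _sample_sizes(target_dup, cfg.cluster_size_dist, rng)
    n_singletons = cfg.n_records - sum(sizes)

    rows, entity_ids, annotations = [], [], {}
    entity = itertools.count()

    def emit(rec: dict, ent: int) -> None:
        rows.append(rec)
        entity_ids.append(ent)

    twin_budget = n_singletons
    for size in sizes:
        ent = next(entity)
        base = _base_person(rng, cfg, villages)
        annotations[ent] = "ordinary"
        emit(dict(base), ent)
        for _ in range(size - 1):
            emit(_duplicate_of(base, rng, cfg.corruption, cfg, villages), ent)
        if twin_budget > 0 and rng.random() < cfg.twin_rate:
            # twin sibling: distinct child sharing the quasi-identifiers
            twin_ent = next(entity)
            twin = dict(base)
            twin["name"] = corrupt_name(base["name"], rng)
            while twin["name"] == base["name"]:
                twin["name"] = _base_person(rng, cfg, villages)["name"]
            if rng.random() < 0.5:
                twin["sex"] = "F" if base["sex"] == "M" else "M"
            annotations[twin_ent] = "twin"
            annotations[ent] = "twin"
            emit(twin, twin_ent)
            twin_budget -= 1

    for _ in range(twin_budget):
        ent = next(entity)
        annotations[ent] = "ordinary"
        emit(_base_person(rng, cfg, villages), ent)

    # placeholder names: the record was made before the child was named
    placeholder_rates = list(cfg.placeholder_rates)
    for rec, ent in zip(rows, entity_ids):
        r = rng.random()
        acc = 0.0
        for token, rate in placeholder_rates:
            acc += rate
            if r < acc:
                rec["name"] = token
                if sum(1 for e in entity_ids if e == ent) > 1:
                    annotations[ent] = "temporary-name"
                break

    # field-completeness thinning (independent per record and field)
    completeness = dict(cfg.completeness)
    for rec in rows:
        for fld, rate in completeness.items():
            if rate < 1.0 and rng.random() >= rate:
                rec[fld] = None

    order = rng.permutation(len(rows))
    record_ids = [f"R{i:06d}" for i in range(len(rows))]
    data = []
    mapping = {}
    for rid, ix in zip(record_ids, order):
        rec = dict(rows[ix])
        rec["record_id"] = rid
        data.append(rec)
        mapping[rid] = entity_ids[ix]
    df = pd.DataFrame(data, columns=RAW_COLUMNS)

    part = Partition.from_labels(list(mapping), [mapping[r] for r in mapping])
    # re-key annotations onto the canonical cluster labels
    label_by_entity = {}
    for rid, ent in mapping.items():
        lab = part.cluster_of(rid)
        label_by_entity[ent] = lab
    ann = {label_by_entity[e]: kind for e, kind in annotations.items() if e in label_by_entity}
    return df, TruthPartition(partition=part, annotations=ann)


def emit_gold_review(df: pd.DataFrame, rules: RuleTable | None = None,
                     reviewer_error_rate: float = 0.02, seed: int = 0,
                     keys: Sequence[str] = DEFAULT_BLOCK_KEYS,
                     n_reviewers: int = 3) -> dict:
    """Simulate a multi-reviewer gold-standard review.

    Each simulated reviewer applies the decision table to every within-block
    candidate pair, with independent decision-flip noise at
    ``reviewer_error_rate``; the consensus links are those all reviewers
    agree are matches (so the consensus match count never exceeds any single
    reviewer's).  Expects a normalized frame.

    Returns a dict with per-reviewer partitions, the consensus partition,
    and the pairwise decision frame.
    """
    if rules is None:
        rules = RuleTable.default()
    rng = np.random.default_rng(seed)
    rows = df.set_index("record_id", drop=False)
    pairs, truth_dec = [], []
    for members in block_records(df, keys).values():
        if len(members) < 2:
            continue
        for ra, rb in itertools.combinations(sorted(members), 2):
            states = tuple(field_state(rows.loc[ra][f], rows.loc[rb][f]) for f in NAME_FIELDS)
            pairs.append((ra, rb))
            truth_dec.append(rules.decision(*states))
    truth_dec = np.asarray(truth_dec, dtype=bool)
    decisions = []
    for _ in range(n_reviewers):
        flips = rng.random(len(pairs)) < reviewer_error_rate
        decisions.append(truth_dec ^ flips)
    consensus = np.logical_and.reduce(decisions) if decisions else truth_dec
    universe = df["record_id"]
    out = {
        "reviewers": [
            Partition.from_links(universe, [p for p, d in zip(pairs, dec) if d])
            for dec in decisions
        ],
        "consensus": Partition.from_links(
            universe, [p for p, d in zip(pairs, consensus) if d]
        ),
        "rule_partition": Partition.from_links(
            universe, [p for p, d in zip(pairs, truth_dec) if d]
        ),
        "decisions": pd.DataFrame(
            {"id1": [a for a, _ in pairs], "id2": [b for _, b in pairs],
             "rule": truth_dec,
             **{f"reviewer_{i + 1}": dec for i, dec in enumerate(decisions)},
             "consensus": consensus},
        ),
    }
    return out
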