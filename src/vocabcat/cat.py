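"""Quota-constrained computerized adaptive test administration.

A session presents a fixed number of stimuli (default 30) drawn from three
kinds under fixed quotas (default 60% binary, 20% multiple-choice, 20%
pseudoword).  After each scored response the ability estimate is updated
(interim EAP under a Normal(0, 3^2) prior, which stays finite for extreme
patterns), and the next real-word item is chosen to match the current
estimate: among unadministered active items of the scheduled kind, the
``randomesque_k`` items nearest in difficulty are found and one is picked
uniformly at random (exposure control).  Pseudowords carry no difficulty
and are drawn uniformly without replacement; claiming to know one is
recorded as a warning but never penalizes the ability estimate.

The kind sequence is a fixed schedule: per-kind targets by the largest
remainder method, spread across the session by largest-remainder spacing,
then shuffled by the session RNG subject to no two pseudowords being
adjacent.  A session transcript is fully determined by (bank, config,
seed, response script).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import scoring
from .item_bank import DEFAULT_QUOTAS, Item, ItemBank, Kind
from .rasch import estimate_ability

__all__ = [
    "AdministrationConfig",
    "SessionState",
    "SessionResult",
    "AdministeredItem",
    "Respondent",
    "ConfigurationError",
    "ProtocolError",
    "SessionError",
    "quota_targets",
    "start_session",
    "select_next_item",
    "record_response",
    "update_ability",
    "is_complete",
    "finalize_session",
    "sessions_to_jsonl",
    "sessions_from_jsonl",
]

KIND_ORDER = (Kind.BINARY, Kind.MULTIPLE_CHOICE, Kind.PSEUDOWORD)


class ConfigurationError(ValueError):
    """The bank cannot support the requested administration."""


class ProtocolError(RuntimeError):
    """A response arrived out of protocol (wrong item, malformed raw)."""


class SessionError(RuntimeError):
    """The session is not in a state that allows the requested operation."""


@dataclass(frozen=True)
class AdministrationConfig:
    test_length: int = 30
    quotas: Mapping[Kind, float] = field(
        default_factory=lambda: dict(DEFAULT_QUOTAS)
    )
    randomesque_k: int = 3
    initial_theta: float = 0.0
    prior: tuple[float, float] = (0.0, 3.0)
    seed: int | None = None
    #: score a wrong synonym choice as incorrect for ability (the default);
    #: if False it is left unscored and affects only the attention index.
    mc_wrong_scores_zero: bool = True

    def __post_init__(self) -> None:
        if self.test_length < len(self.quotas):
            raise ValueError("test_length must be >= number of kinds")
        if any(q < 0 for q in self.quotas.values()):
            raise ValueError("quotas must be nonnegative")
        if abs(sum(self.quotas.values()) - 1.0) > 1e-9:
            raise ValueError("quotas must sum to 1")
        if self.randomesque_k < 1:
            raise ValueError("randomesque_k must be >= 1")


@dataclass(frozen=True)
class Respondent:
    age: float
    nativeness: str  # "native" | "non_native"
    honesty_confirmed: bool = True


@dataclass(frozen=True)
class AdministeredItem:
    item_id: str
    kind: Kind
    answer: str                      # "know" | "dont_know"
    option: str | None               # chosen MC option text, if any
    scored: int | None               # 0/1, or None when unscored
    presented_options: tuple[str, ...] | None
    theta: float | None = None       # interim estimate after this response
    se: float | None = None


@dataclass
class SessionState:
    config: AdministrationConfig
    schedule: list[Kind]
    quota_remaining: dict[Kind, int]
    rng: np.random.Generator
    theta: float
    se: float
    administered: list[AdministeredItem] = field(default_factory=list)
    theta_trajectory: list[tuple[float, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    pending: Item | None = None
    pending_options: tuple[str, ...] | None = None
    started_at: float | None = None
    ended_at: float | None = None

    @property
    def administered_ids(self) -> set[str]:
        return {a.item_id for a in self.administered}

    def scored_pairs(self, bank: ItemBank) -> list[tuple[float, int]]:
        pairs = []
        for rec in self.administered:
            if rec.scored is not None:
                b = bank.get(rec.item_id).difficulty
                pairs.append((float(b), int(rec.scored)))
        return pairs


@dataclass(frozen=True)
class SessionResult:
    session_id: str
    theta: float
    theta_se: float
    vocabulary_size: int
    attention_index: float
    trustworthy: bool
    duration: float
    respondent: Respondent
    item_log: tuple[AdministeredItem, ...]
    warnings: tuple[str, ...] = ()
    ended_at: float | None = None


# ---------------------------------------------------------------------------
# schedule construction


def quota_targets(config: AdministrationConfig) -> dict[Kind, int]:
    """Integer per-kind item targets by the largest remainder method."""
    L = config.test_length
    raw = {k: config.quotas.get(k, 0.0) * L for k in KIND_ORDER}
    targets = {k: int(np.floor(v)) for k, v in raw.items()}
    short = L - sum(targets.values())
    by_fraction = sorted(
        KIND_ORDER, key=lambda k: (-(raw[k] - targets[k]), KIND_ORDER.index(k))
    )
    for k in by_fraction[:short]:
        targets[k] += 1
    return targets


def _spaced_schedule(targets: Mapping[Kind, int]) -> list[Kind]:
    """Deterministic largest-remainder spacing of kinds across the session."""
    L = sum(targets.values())
    placed = {k: 0 for k in targets}
    out: list[Kind] = []
    for pos in range(1, L + 1):
        k = max(
            (k for k in KIND_ORDER if targets.get(k, 0) > 0),
            key=lambda k: targets[k] * pos / L - placed[k],
        )
        out.append(k)
        placed[k] += 1
    return out


def _build_schedule(
    targets: Mapping[Kind, int], rng: np.random.Generator, max_tries: int = 200
) -> list[Kind]:
    base = _spaced_schedule(targets)
    arr = np.array([KIND_ORDER.index(k) for k in base])
    pseudo = KIND_ORDER.index(Kind.PSEUDOWORD)
    for _ in range(max_tries):
        perm = arr[rng.permutation(arr.size)]
        adjacent = np.any((perm[:-1] == pseudo) & (perm[1:] == pseudo))
        if not adjacent:
            return [KIND_ORDER[i] for i in perm]
    return base  # spacing already satisfies the adjacency constraint


# ---------------------------------------------------------------------------
# session operations


def start_session(bank: ItemBank, config: AdministrationConfig) -> SessionState:
    """Open an empty session: quota targets, schedule, seeded RNG."""
    targets = quota_targets(config)
    for kind, target in targets.items():
        pool = bank.active_items(kind)
        if kind is not Kind.PSEUDOWORD:
            pool = [i for i in pool if i.difficulty is not None]
        if len(pool) < target:
            raise ConfigurationError(
                f"bank has {len(pool)} usable {kind.value} items; {target} required"
            )
    if bank.conversion_b is None or bank.conversion_c is None:
        raise ConfigurationError("bank carries no conversion coefficients")
    rng = np.random.default_rng(config.seed)
    schedule = _build_schedule(targets, rng)
    return SessionState(
        config=config,
        schedule=schedule,
        quota_remaining=dict(targets),
        rng=rng,
        theta=config.initial_theta,
        se=config.prior[1],
    )


def is_complete(state: SessionState, config: AdministrationConfig | None = None) -> bool:
    cfg = config or state.config
    return len(state.administered) >= cfg.test_length


def _eligible(state: SessionState, bank: ItemBank, kind: Kind) -> list[Item]:
    seen = state.administered_ids
    pool = [i for i in bank.active_items(kind) if i.id not in seen]
    if kind is not Kind.PSEUDOWORD:
        pool = [i for i in pool if i.difficulty is not None]
    return pool


def select_next_item(state: SessionState, bank: ItemBank) -> Item:
    """Pick the next item: scheduled kind, difficulty-matched, randomesque."""
    if is_complete(state):
        raise SessionError("session already complete")
    if state.pending is not None:
        raise ProtocolError(f"item {state.pending.id!r} is awaiting a response")
    pos = len(state.administered)
    scheduled = state.schedule[pos]
    candidates = [scheduled] + [
        k for k in KIND_ORDER if k is not scheduled
    ]
    item: Item | None = None
    for kind in candidates:
        if state.quota_remaining.get(kind, 0) <= 0:
            continue
        pool = _eligible(state, bank, kind)
        if not pool:
            continue
        if kind is Kind.PSEUDOWORD:
            pool = sorted(pool, key=lambda i: i.id)
            item = pool[int(state.rng.integers(len(pool)))]
        else:
            pool = sorted(
                pool, key=lambda i: (abs(i.difficulty - state.theta), i.difficulty, i.id)
            )
            top = pool[: min(state.config.randomesque_k, len(pool))]
            item = top[int(state.rng.integers(len(top)))]
        break
    if item is None:
        raise SessionError("no eligible item of any kind with remaining quota")
    state.pending = item
    if item.kind is Kind.MULTIPLE_CHOICE:
        order = state.rng.permutation(4)
        state.pending_options = tuple(item.options[j] for j in order)
    else:
        state.pending_options = None
    return item


def _normalize_raw(raw) -> dict:
    if isinstance(raw, str):
        return {"answer": raw, "option": None}
    if isinstance(raw, dict):
        return {"answer": raw.get("answer"), "option": raw.get("option")}
    raise ProtocolError(f"unrecognized raw response {raw!r}")


def record_response(
    state: SessionState, item: Item, raw, bank: ItemBank
) -> SessionState:
    """Score a raw response to the last selected item and update ability.

    Binary: "know" scores 1, "dont_know" scores 0.  Multiple-choice:
    "dont_know" scores 0; "know" requires a chosen option and scores 1 only
    for the designated synonym.  Pseudowords are never scored; claiming to
    know one appends a warning token.  The interim ability is re-estimated
    only after scored responses.
    """
    if state.pending is None or state.pending.id != item.id:
        raise ProtocolError(f"item {item.id!r} was not the pending item")
    parsed = _normalize_raw(raw)
    answer = parsed["answer"]
    option = parsed["option"]
    if answer not in {"know", "dont_know"}:
        raise ProtocolError(f"answer must be 'know' or 'dont_know', got {answer!r}")

    scored: int | None
    if item.kind is Kind.BINARY:
        scored = 1 if answer == "know" else 0
        option = None
    elif item.kind is Kind.MULTIPLE_CHOICE:
        if answer == "dont_know":
            scored = 0
            option = None
        else:
            if option is None or option not in state.pending_options:
                raise ProtocolError(
                    f"multiple_choice 'know' response to {item.id!r} lacks a "
                    "chosen option"
                )
            if option == item.correct_text:
                scored = 1
            else:
                scored = 0 if state.config.mc_wrong_scores_zero else None
    else:  # pseudoword
        scored = None
        option = None
        if answer == "know":
            state.warnings.append(f"pseudoword-claimed-known:{item.id}")

    presented = state.pending_options
    state.pending = None
    state.pending_options = None
    state.quota_remaining[item.kind] -= 1
    rec = AdministeredItem(
        item_id=item.id,
        kind=item.kind,
        answer=answer,
        option=option,
        scored=scored,
        presented_options=presented,
    )
    state.administered.append(rec)
    if scored is not None:
        theta, se = update_ability(state, bank)
        state.administered[-1] = replace(rec, theta=theta, se=se)
    return state


def update_ability(
    state: SessionState, bank: ItemBank, config: AdministrationConfig | None = None
) -> tuple[float, float]:
    """Interim EAP ability over the scored responses; appended to trajectory."""
    cfg = config or state.config
    pairs = state.scored_pairs(bank)
    if not pairs:
        raise SessionError("no scored responses yet")
    theta, se = estimate_ability(pairs, method="eap", prior=cfg.prior)
    state.theta, state.se = theta, se
    state.theta_trajectory.append((theta, se))
    return theta, se


def _attention_counts(log: Sequence[AdministeredItem]) -> scoring.AttentionCounts:
    """Control-item counts for the attention index.

    Pseudowords: ``x`` of ``ax`` presented were rejected ("don't know").
    Multiple-choice: the four-option definition question is only presented
    once "I know" has been claimed, so ``ay`` counts definition stages
    reached and ``y`` those answered with the designated synonym.  This
    makes the index a measure of response care — definition correctness
    *given* a knowledge claim — rather than of ability, which is what lets
    it separate careless from attentive respondents at every proficiency
    level.
    """
    ax = sum(1 for r in log if r.kind is Kind.PSEUDOWORD)
    x = sum(
        1 for r in log if r.kind is Kind.PSEUDOWORD and r.answer == "dont_know"
    )
    reached = [
        r
        for r in log
        if r.kind is Kind.MULTIPLE_CHOICE and r.answer == "know" and r.option is not None
    ]
    ay = len(reached)
    # a reached definition stage is correct iff it scored 1 (a wrong choice
    # scores 0 or, under mc_wrong_scores_zero=False, stays unscored)
    y = sum(1 for r in reached if r.scored == 1)
    return scoring.AttentionCounts(x=x, ax=ax, y=y, ay=ay)


def _default_session_id(log: Sequence[AdministeredItem]) -> str:
    digest = hashlib.blake2b(
        json.dumps([(r.item_id, r.answer, r.option) for r in log]).encode(),
        digest_size=6,
    )
    return digest.hexdigest()


def finalize_session(
    state: SessionState,
    bank: ItemBank,
    respondent: Respondent,
    *,
    duration: float | None = None,
    session_id: str | None = None,
    ended_at: float | None = None,
    trust_threshold: float = scoring.DEFAULT_TRUST_THRESHOLD,
) -> SessionResult:
    """Close a completed session: ability, words, attention, trust flag."""
    if not is_complete(state):
        raise SessionError(
            f"session has {len(state.administered)} of "
            f"{state.config.test_length} items"
        )
    if state.theta_trajectory:
        theta, se = state.theta_trajectory[-1]
    else:
        theta, se = state.config.prior
    coeffs = scoring.ConversionCoefficients(
        a=bank.total_lexicon_size, b=bank.conversion_b, c=bank.conversion_c
    )
    words = scoring.logits_to_words(theta, coeffs)
    counts = _attention_counts(state.administered)
    index = scoring.attention_index(counts)
    if ended_at is None:
        ended_at = state.ended_at
    if duration is None:
        if state.started_at is not None and ended_at is not None:
            duration = ended_at - state.started_at
        else:
            duration = float("nan")
    return SessionResult(
        session_id=session_id or _default_session_id(state.administered),
        theta=float(theta),
        theta_se=float(se),
        vocabulary_size=words,
        attention_index=float(index),
        trustworthy=scoring.is_trustworthy(index, trust_threshold),
        duration=float(duration),
        respondent=respondent,
        item_log=tuple(state.administered),
        warnings=tuple(state.warnings),
        ended_at=ended_at,
    )


# ---------------------------------------------------------------------------
# JSONL persistence (one session result per line)


def _result_to_dict(result: SessionResult) -> dict:
    return {
        "session_id": result.session_id,
        "theta": result.theta,
        "theta_se": result.theta_se,
        "vocabulary_size": result.vocabulary_size,
        "attention_index": result.attention_index,
        "trustworthy": result.trustworthy,
        "duration": result.duration,
        "ended_at": result.ended_at,
        "warnings": list(result.warnings),
        "respondent": {
            "age": result.respondent.age,
            "nativeness": result.respondent.nativeness,
            "honesty_confirmed": result.respondent.honesty_confirmed,
        },
        "items": [
            {
                "item_id": r.item_id,
                "kind": r.kind.value,
                "answer": r.answer,
                "option": r.option,
                "scored": r.scored,
                "presented_options": list(r.presented_options)
                if r.presented_options is not None
                else None,
                "theta": r.theta,
                "se": r.se,
            }
            for r in result.item_log
        ],
    }


def _dict_to_result(doc: dict) -> SessionResult:
    resp = doc["respondent"]
    log = tuple(
        AdministeredItem(
            item_id=r["item_id"],
            kind=Kind(r["kind"]),
            answer=r["answer"],
            option=r.get("option"),
            scored=r.get("scored"),
            presented_options=tuple(r["presented_options"])
            if r.get("presented_options") is not None
            else None,
            theta=r.get("theta"),
            se=r.get("se"),
        )
        for r in doc.get("items", [])
    )
    return SessionResult(
        session_id=doc["session_id"],
        theta=doc["theta"],
        theta_se=doc["theta_se"],
        vocabulary_size=doc["vocabulary_size"],
        attention_index=doc["attention_index"],
        trustworthy=doc["trustworthy"],
        duration=doc["duration"],
        respondent=Respondent(
            age=resp["age"],
            nativeness=resp["nativeness"],
            honesty_confirmed=resp.get("honesty_confirmed", True),
        ),
        item_log=log,
        warnings=tuple(doc.get("warnings", ())),
        ended_at=doc.get("ended_at"),
    )


def sessions_to_jsonl(path: str | Path, results: Iterable[SessionResult]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for result in results:
            fh.write(json.dumps(_result_to_dict(result), ensure_ascii=False) + "\n")


def sessions_from_jsonl(path: str | Path) -> list[SessionResult]:
    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(_dict_to_result(json.loads(line)))
    return out
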