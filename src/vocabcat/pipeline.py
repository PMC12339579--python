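"""Session filtering, repeat detection, and bank recalibration.

Accumulated session logs are turned into an updated item bank in five
stages: (1) rule-based session filtering — honesty confirmation, attention
index, test duration, reported age, then a per-nativeness-group mean +/- k*SD
outlier rule on vocabulary size computed over the sessions surviving the
earlier rules; (2) assembly of the person x item response matrix (scored
binary and multiple-choice responses only; pseudowords and unscored entries
stay missing); (3) marginal maximum likelihood Rasch recalibration;
(4) misfit flagging (mean-square and standardized-fit exceedance jointly
by default); (5) write-back of difficulties and refit of the
rank-vs-difficulty conversion coefficients on the surviving active items.

All thresholds are strict inequalities (a session is excluded iff strictly
below a floor / outside the band), and the outlier rule runs once, last, so
group statistics are not polluted by attention or duration artifacts.
Suspected repeat attempts (same reported age and nativeness within a short
window) are flagged for inspection but never removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import scoring
from .cat import SessionResult
from .item_bank import Item, ItemBank, Kind
from .rasch import (
    CalibrationConfig,
    CalibrationResult,
    FitStatistics,
    ResponseMatrix,
    calibrate_items,
    fit_statistics,
)

__all__ = [
    "FilterRules",
    "FilterReport",
    "PipelineStageError",
    "UnknownItemError",
    "filter_sessions",
    "detect_repeats",
    "assemble_matrix",
    "flag_misfitting_items",
    "recalibrate",
    "RecalibrationOutcome",
]


class PipelineStageError(RuntimeError):
    """An error in a named recalibration stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class UnknownItemError(KeyError):
    """A session log references an item id absent from the bank."""


@dataclass(frozen=True)
class FilterRules:
    min_attention: float = 70.0
    min_duration: float = 60.0
    min_age: float = 7.0
    outlier_sd_multiplier: float = 2.0
    require_honesty_confirmation: bool = True

    def __post_init__(self) -> None:
        if min(self.min_attention, self.min_duration, self.min_age) < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.outlier_sd_multiplier < 0:
            raise ValueError("outlier_sd_multiplier must be nonnegative")


@dataclass
class FilterReport:
    kept: tuple[str, ...]
    excluded: dict[str, tuple[str, ...]]
    rule_counts: dict[str, int]
    warnings: tuple[str, ...] = ()

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.excluded)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"session_id": sid, "kept": True, "reasons": ""} for sid in self.kept
        ] + [
            {"session_id": sid, "kept": False, "reasons": ";".join(reasons)}
            for sid, reasons in self.excluded.items()
        ]
        return pd.DataFrame(rows, columns=["session_id", "kept", "reasons"])


def _rule_reasons(session: SessionResult, rules: FilterRules) -> list[str]:
    """Deterministic per-session rules (everything except the outlier rule)."""
    reasons = []
    if rules.require_honesty_confirmation and not session.respondent.honesty_confirmed:
        reasons.append("honesty")
    if session.attention_index < rules.min_attention:
        reasons.append("attention")
    if np.isfinite(session.duration) and session.duration < rules.min_duration:
        reasons.append("duration")
    if session.respondent.age < rules.min_age:
        reasons.append("age")
    return reasons


def filter_sessions(
    sessions: Sequence[SessionResult], rules: FilterRules | None = None
) -> FilterReport:
    """Partition sessions into kept and excluded, with per-session reasons.

    Rules apply in order: honesty confirmation, attention index, duration,
    age, then the per-nativeness-group mean +/- k*SD vocabulary-size rule
    computed on the sessions surviving the earlier rules.  A nativeness
    group with fewer than 3 survivors skips the outlier rule (warning).
    """
    rules = rules or FilterRules()
    reasons: dict[str, list[str]] = {}
    for s in sessions:
        reasons[s.session_id] = _rule_reasons(s, rules)
    survivors = [s for s in sessions if not reasons[s.session_id]]

    warn_list: list[str] = []
    for group in sorted({s.respondent.nativeness for s in survivors}):
        members = [s for s in survivors if s.respondent.nativeness == group]
        if len(members) < 3:
            msg = f"nativeness group {group!r} has {len(members)} survivors; outlier rule skipped"
            warnings.warn(msg)
            warn_list.append(msg)
            continue
        values = np.array([s.vocabulary_size for s in members], dtype=float)
        mean, sd = values.mean(), values.std(ddof=1)
        k = rules.outlier_sd_multiplier
        for s in members:
            v = s.vocabulary_size
            if v < mean - k * sd or v > mean + k * sd:
                reasons[s.session_id].append("vocabulary_outlier")

    kept = tuple(s.session_id for s in sessions if not reasons[s.session_id])
    excluded = {
        s.session_id: tuple(reasons[s.session_id])
        for s in sessions
        if reasons[s.session_id]
    }
    rule_counts: dict[str, int] = {}
    for rs in excluded.values():
        for r in rs:
            rule_counts[r] = rule_counts.get(r, 0) + 1
    return FilterReport(
        kept=kept,
        excluded=excluded,
        rule_counts=rule_counts,
        warnings=tuple(warn_list),
    )


def detect_repeats(
    sessions: Sequence[SessionResult], window: float = 300.0
) -> list[tuple[str, ...]]:
    """Group suspected repeat attempts; flagged, never removed.

    Sessions whose end timestamps fall within *window* seconds of one
    another and whose reported (age, nativeness) match are chained
    transitively into maximal groups; only groups of two or more are
    returned.  Sessions without a timestamp are skipped with a warning.
    """
    keyed: dict[tuple[float, str], list[SessionResult]] = {}
    for s in sessions:
        if s.ended_at is None:
            warnings.warn(f"session {s.session_id!r} has no end timestamp; skipped")
            continue
        keyed.setdefault((s.respondent.age, s.respondent.nativeness), []).append(s)
    groups: list[tuple[str, ...]] = []
    for members in keyed.values():
        members.sort(key=lambda s: s.ended_at)
        chain = [members[0]]
        for s in members[1:]:
            if s.ended_at - chain[-1].ended_at <= window:
                chain.append(s)
            else:
                if len(chain) > 1:
                    groups.append(tuple(m.session_id for m in chain))
                chain = [s]
        if len(chain) > 1:
            groups.append(tuple(m.session_id for m in chain))
    return groups


def assemble_matrix(
    sessions: Sequence[SessionResult], bank: ItemBank
) -> ResponseMatrix:
    """Build the person x item matrix from scored session responses.

    Columns are the bank items with at least one scored response, in bank
    order; pseudoword and unscored entries stay missing by design.
    """
    bank_ids = {item.id for item in bank.items}
    used: set[str] = set()
    for s in sessions:
        for rec in s.item_log:
            if rec.item_id not in bank_ids:
                raise UnknownItemError(
                    f"session {s.session_id!r} references unknown item {rec.item_id!r}"
                )
            if rec.scored is not None:
                used.add(rec.item_id)
    item_ids = tuple(item.id for item in bank.items if item.id in used)
    col = {iid: j for j, iid in enumerate(item_ids)}
    scores = np.full((len(sessions), len(item_ids)), np.nan)
    for i, s in enumerate(sessions):
        for rec in s.item_log:
            if rec.scored is not None:
                scores[i, col[rec.item_id]] = float(rec.scored)
    return ResponseMatrix(
        tuple(s.session_id for s in sessions), item_ids, scores
    )


def flag_misfitting_items(
    fit: Iterable[FitStatistics],
    mse_cutoff: float = 1.3,
    z_cutoff: float = 2.0,
    rule: str = "and",
) -> list[str]:
    """Item ids whose fit exceeds the misfit cutoffs (strict inequalities).

    With ``rule="and"`` (default) an item is flagged iff a mean-square
    exceeds *mse_cutoff* AND a standardized fit exceeds *z_cutoff* in
    absolute value; ``rule="or"`` flags on either exceedance alone.
    """
    if rule not in {"and", "or"}:
        raise ValueError("rule must be 'and' or 'or'")
    flagged = []
    for f in fit:
        mse_hit = f.infit_mse > mse_cutoff or f.outfit_mse > mse_cutoff
        z_hit = abs(f.std_infit) > z_cutoff or abs(f.std_outfit) > z_cutoff
        hit = (mse_hit and z_hit) if rule == "and" else (mse_hit or z_hit)
        if hit:
            flagged.append(f.entity_id)
    return flagged


@dataclass
class RecalibrationOutcome:
    bank: ItemBank
    calibration: CalibrationResult
    filter_report: FilterReport
    flagged_items: tuple[str, ...]
    conversion: scoring.ConversionFit | None


def recalibrate(
    bank: ItemBank,
    sessions: Sequence[SessionResult],
    rules: FilterRules | None = None,
    *,
    calibration_config: CalibrationConfig | None = None,
    misfit_rule: str = "and",
    mse_cutoff: float = 1.3,
    z_cutoff: float = 2.0,
) -> RecalibrationOutcome:
    """Filter sessions, recalibrate the bank, and exclude misfitting items.

    Returns the updated bank (new difficulties/SEs on active items,
    misfitting items deactivated, conversion coefficients refit on the
    active calibrated items), the calibration result, and the filter
    report.  Pseudowords never acquire difficulties.
    """
    rules = rules or FilterRules()
    report = filter_sessions(sessions, rules)
    kept_ids = set(report.kept)
    kept = [s for s in sessions if s.session_id in kept_ids]
    if not kept:
        raise PipelineStageError("calibration", "no sessions kept by the filter")

    try:
        matrix = assemble_matrix(kept, bank)
    except UnknownItemError as exc:
        raise PipelineStageError("assemble", str(exc)) from exc
    try:
        calib = calibrate_items(matrix, calibration_config)
    except ValueError as exc:
        raise PipelineStageError("calibration", str(exc)) from exc

    flagged = flag_misfitting_items(
        calib.item_fit, mse_cutoff=mse_cutoff, z_cutoff=z_cutoff, rule=misfit_rule
    )
    flagged_set = set(flagged)

    new_items: list[Item] = []
    for item in bank.items:
        est = calib.item_difficulties.get(item.id)
        if est is not None and item.kind is not Kind.PSEUDOWORD:
            item = replace(item, difficulty=est[0], difficulty_se=est[1])
        if item.id in flagged_set:
            item = replace(item, active=False)
        new_items.append(item)

    pairs = [
        (float(i.frequency_rank), float(i.difficulty))
        for i in new_items
        if i.active and i.difficulty is not None and i.frequency_rank is not None
    ]
    conversion: scoring.ConversionFit | None = None
    new_b, new_c = bank.conversion_b, bank.conversion_c
    if len(pairs) >= 3 and len({d for _, d in pairs}) >= 2:
        conversion = scoring.fit_conversion(pairs, a=bank.total_lexicon_size)
        new_b = conversion.coefficients.b
        new_c = conversion.coefficients.c
    else:
        warnings.warn("too few (rank, difficulty) pairs; conversion kept as-is")

    new_bank = replace(
        bank, items=new_items, conversion_b=new_b, conversion_c=new_c
    )
    return RecalibrationOutcome(
        bank=new_bank,
        calibration=calib,
        filter_report=report,
        flagged_items=tuple(flagged),
        conversion=conversion,
    )
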