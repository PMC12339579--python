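"""Item banks for adaptive yes/no vocabulary testing.

An item bank holds the calibrated stimuli administered by the adaptive
engine: *binary* yes/no words, *multiple-choice* words (a synonym plus
three distractors), and *pseudowords* used purely as attention controls.
Binary and multiple-choice items carry a Rasch difficulty in logits and a
corpus frequency rank; pseudowords carry neither.  The bank also stores
bank-level administration quotas (default 60/20/20) and the coefficients of
the logistic logit-to-words conversion.

Banks round-trip through CSV (one row per item; bank-level metadata takes
package defaults) and JSON (items plus a ``meta`` object preserving quotas
and conversion coefficients).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Kind",
    "Item",
    "ItemBank",
    "BankError",
    "BankParseError",
    "BankValidationError",
    "load_bank",
    "save_bank",
    "DEFAULT_QUOTAS",
    "DEFAULT_LEXICON_SIZE",
]

DEFAULT_LEXICON_SIZE = 140_000

CSV_COLUMNS = [
    "id", "text", "kind", "difficulty", "difficulty_se", "frequency_rank",
    "opt1", "opt2", "opt3", "opt4", "correct_opt", "active",
]


class Kind(str, Enum):
    """Stimulus kind administered by the test."""

    BINARY = "binary"
    MULTIPLE_CHOICE = "multiple_choice"
    PSEUDOWORD = "pseudoword"


DEFAULT_QUOTAS: Mapping[Kind, float] = {
    Kind.BINARY: 0.6,
    Kind.MULTIPLE_CHOICE: 0.2,
    Kind.PSEUDOWORD: 0.2,
}


class BankError(Exception):
    """Base class for item-bank errors."""


class BankParseError(BankError):
    """A bank file could not be parsed."""


class BankValidationError(BankError):
    """A bank or item violates a structural invariant."""


@dataclass(frozen=True)
class Item:
    """A single stimulus.

    Parameters
    ----------
    id : str
        Unique token within a bank.
    text : str
        The stimulus string shown to the test-taker.
    kind : Kind
        Binary, multiple-choice, or pseudoword.
    difficulty : float, optional
        Rasch difficulty in logits.  Absent for pseudowords and for items
        not yet calibrated.
    difficulty_se : float, optional
        Standard error of the difficulty, logits.
    frequency_rank : int, optional
        Corpus rank from most (1) to least frequent.  Absent for pseudowords.
    options : tuple of str, optional
        For multiple-choice items only: exactly four answer strings.
    correct_option : int, optional
        0-based index into ``options`` of the designated synonym.
    active : bool
        False once the item has been excluded (e.g., by misfit).
    """

    id: str
    text: str
    kind: Kind
    difficulty: float | None = None
    difficulty_se: float | None = None
    frequency_rank: int | None = None
    options: tuple[str, str, str, str] | None = None
    correct_option: int | None = None
    active: bool = True

    def validate(self) -> None:
        if not self.id:
            raise BankValidationError("item with empty id")
        if self.kind is Kind.MULTIPLE_CHOICE:
            if self.options is None or len(self.options) != 4:
                raise BankValidationError(
                    f"item {self.id!r}: multiple_choice items need exactly 4 options"
                )
            if self.correct_option is None or not 0 <= self.correct_option <= 3:
                raise BankValidationError(
                    f"item {self.id!r}: exactly one option must be marked correct"
                )
        else:
            if self.options is not None or self.correct_option is not None:
                raise BankValidationError(
                    f"item {self.id!r}: only multiple_choice items carry options"
                )
        if self.kind is Kind.PSEUDOWORD:
            if self.difficulty is not None or self.frequency_rank is not None:
                raise BankValidationError(
                    f"item {self.id!r}: pseudowords carry no difficulty or rank"
                )
        if self.difficulty is not None and not math.isfinite(self.difficulty):
            raise BankValidationError(f"item {self.id!r}: non-finite difficulty")
        if self.difficulty_se is not None and self.difficulty_se < 0:
            raise BankValidationError(f"item {self.id!r}: negative difficulty SE")
        if self.frequency_rank is not None and self.frequency_rank < 1:
            raise BankValidationError(f"item {self.id!r}: frequency_rank must be >= 1")

    @property
    def correct_text(self) -> str | None:
        if self.options is None or self.correct_option is None:
            return None
        return self.options[self.correct_option]


@dataclass
class ItemBank:
    """A collection of items plus bank-level administration metadata."""

    items: list[Item] = field(default_factory=list)
    quotas: dict[Kind, float] = field(
        default_factory=lambda: dict(DEFAULT_QUOTAS)
    )
    total_lexicon_size: int = DEFAULT_LEXICON_SIZE
    conversion_b: float | None = None
    conversion_c: float | None = None
    version: str = "0"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        seen: set[str] = set()
        for item in self.items:
            item.validate()
            if item.id in seen:
                raise BankValidationError(f"duplicate item id {item.id!r}")
            seen.add(item.id)
        if any(q < 0 for q in self.quotas.values()):
            raise BankValidationError("quotas must be nonnegative")
        if abs(sum(self.quotas.values()) - 1.0) > 1e-9:
            raise BankValidationError("quotas must sum to 1")
        if self.total_lexicon_size <= 0:
            raise BankValidationError("total_lexicon_size must be positive")

    # -- access helpers -------------------------------------------------

    def get(self, item_id: str) -> Item:
        for item in self.items:
            if item.id == item_id:
                return item
        raise KeyError(item_id)

    def __contains__(self, item_id: str) -> bool:
        return any(item.id == item_id for item in self.items)

    def active_items(self, kind: Kind | None = None) -> list[Item]:
        out = [i for i in self.items if i.active]
        if kind is not None:
            out = [i for i in out if i.kind is kind]
        return out

    def counts_by_kind(self) -> dict[Kind, int]:
        counts = {k: 0 for k in Kind}
        for item in self.items:
            counts[item.kind] += 1
        return counts

    def with_items(self, items: Iterable[Item]) -> "ItemBank":
        return replace(self, items=list(items))


# ---------------------------------------------------------------------------
# serialization


def _item_to_row(item: Item) -> dict[str, str]:
    row = {c: "" for c in CSV_COLUMNS}
    row["id"] = item.id
    row["text"] = item.text
    row["kind"] = item.kind.value
    if item.difficulty is not None:
        row["difficulty"] = repr(float(item.difficulty))
    if item.difficulty_se is not None:
        row["difficulty_se"] = repr(float(item.difficulty_se))
    if item.frequency_rank is not None:
        row["frequency_rank"] = str(int(item.frequency_rank))
    if item.options is not None:
        for j, opt in enumerate(item.options):
            row[f"opt{j + 1}"] = opt
        row["correct_opt"] = str(item.correct_option + 1)
    row["active"] = "true" if item.active else "false"
    return row


def _row_to_item(row: Mapping[str, str], where: str) -> Item:
    def opt_float(key: str) -> float | None:
        raw = str(row.get(key, "") or "").strip()
        if raw == "":
            return None
        try:
            return float(raw)
        except ValueError as exc:
            raise BankParseError(f"{where}: bad {key} value {raw!r}") from exc

    def opt_int(key: str) -> int | None:
        raw = str(row.get(key, "") or "").strip()
        if raw == "":
            return None
        try:
            return int(raw)
        except ValueError as exc:
            raise BankParseError(f"{where}: bad {key} value {raw!r}") from exc

    kind_raw = str(row.get("kind", "")).strip()
    try:
        kind = Kind(kind_raw)
    except ValueError as exc:
        raise BankParseError(f"{where}: unknown kind {kind_raw!r}") from exc

    opts = [str(row.get(f"opt{j}", "") or "") for j in range(1, 5)]
    has_opts = any(o != "" for o in opts)
    correct = opt_int("correct_opt")
    options: tuple[str, str, str, str] | None = None
    correct_option: int | None = None
    if has_opts or correct is not None:
        if not all(o != "" for o in opts):
            raise BankParseError(f"{where}: multiple_choice rows need 4 options")
        if correct is None or not 1 <= correct <= 4:
            raise BankParseError(f"{where}: correct_opt must be 1..4")
        options = (opts[0], opts[1], opts[2], opts[3])
        correct_option = correct - 1

    active_raw = str(row.get("active", "true") or "true").strip().lower()
    if active_raw not in {"true", "false", ""}:
        raise BankParseError(f"{where}: bad active value {active_raw!r}")

    return Item(
        id=str(row.get("id", "")).strip(),
        text=str(row.get("text", "") or ""),
        kind=kind,
        difficulty=opt_float("difficulty"),
        difficulty_se=opt_float("difficulty_se"),
        frequency_rank=opt_int("frequency_rank"),
        options=options,
        correct_option=correct_option,
        active=active_raw != "false",
    )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in {"csv", "json"}:
            raise ValueError(f"unknown bank format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"csv", "json"}:
        return suffix
    raise ValueError(f"cannot infer bank format from {path}")


def save_bank(bank: ItemBank, path: str | Path, format: str | None = None) -> None:
    """Write *bank* to disk as CSV or JSON.

    CSV carries one row per item; bank-level metadata (quotas, conversion
    coefficients) is carried only by the JSON format.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        frame = pd.DataFrame([_item_to_row(i) for i in bank.items], columns=CSV_COLUMNS)
        frame.to_csv(path, index=False, encoding="utf-8")
        return
    doc = {
        "meta": {
            "quotas": {k.value: v for k, v in bank.quotas.items()},
            "total_lexicon_size": bank.total_lexicon_size,
            "conversion_b": bank.conversion_b,
            "conversion_c": bank.conversion_c,
            "version": bank.version,
        },
        "items": [
            {
                "id": i.id,
                "text": i.text,
                "kind": i.kind.value,
                "difficulty": i.difficulty,
                "difficulty_se": i.difficulty_se,
                "frequency_rank": i.frequency_rank,
                "options": list(i.options) if i.options is not None else None,
                "correct_option": i.correct_option,
                "active": i.active,
            }
            for i in bank.items
        ],
    }
    path.write_text(json.dumps(doc, ensure_ascii=False, indent=1), encoding="utf-8")


def load_bank(path: str | Path, format: str | None = None) -> ItemBank:
    """Load a validated :class:`ItemBank` from CSV or JSON."""
    path = Path(path)
    if not path.exists():
        raise BankParseError(f"bank file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "csv":
        try:
            frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise BankParseError(f"{path}: {exc}") from exc
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise BankParseError(f"{path}: missing columns {missing}")
        items = [
            _row_to_item(row, f"{path} row {idx + 2}")
            for idx, row in frame.iterrows()
        ]
        return ItemBank(items=items)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise BankParseError(f"{path}: {exc}") from exc
    meta = doc.get("meta", {})
    items = []
    for idx, rec in enumerate(doc.get("items", [])):
        try:
            kind = Kind(rec["kind"])
            options = rec.get("options")
            items.append(
                Item(
                    id=str(rec["id"]),
                    text=str(rec.get("text", "")),
                    kind=kind,
                    difficulty=rec.get("difficulty"),
                    difficulty_se=rec.get("difficulty_se"),
                    frequency_rank=rec.get("frequency_rank"),
                    options=tuple(options) if options is not None else None,
                    correct_option=rec.get("correct_option"),
                    active=bool(rec.get("active", True)),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise BankParseError(f"{path}: item #{idx}: {exc}") from exc
    quotas = {Kind(k): float(v) for k, v in meta.get("quotas", {}).items()} or dict(
        DEFAULT_QUOTAS
    )
    return ItemBank(
        items=items,
        quotas=quotas,
        total_lexicon_size=int(meta.get("total_lexicon_size", DEFAULT_LEXICON_SIZE)),
        conversion_b=meta.get("conversion_b"),
        conversion_c=meta.get("conversion_c"),
        version=str(meta.get("version", "0")),
    )
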