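"""Benchmark harness: top/any precision-recall over labeled records.

Each evaluation record is an entity string with an expected grounding
and, optionally, context text, an entity-type category and a set of
equivalent identifiers (the same concept registered in a different
namespace).  Two conditions are scored in one pass:

* **top** (strict): the first-ranked match is the expected grounding
  or one of its equivalents;
* **any** (permissive): any returned match is acceptable, regardless
  of rank.

Precision counts hits over records that received at least one match;
recall counts hits over all records, so an ungrounded record hurts
recall only.  This denominator convention is applied consistently for
both conditions and all categories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .stringmatch import Grounder, canonicalize

__all__ = [
    "EvalRecord",
    "EvalResult",
    "Prf",
    "evaluate",
    "load_eval_records_jsonl",
    "load_equivalences",
    "apply_equivalences",
]


@dataclass(frozen=True)
class EvalRecord:
    """One labeled benchmark entry."""

    entity_text: str
    expected: tuple[str, str]
    context: str | None = None
    category: str | None = None
    equivalents: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if not self.entity_text:
            raise ValueError("entity_text must be non-empty")
        if not self.expected[0] or not self.expected[1]:
            raise ValueError("expected grounding must be non-empty")
        object.__setattr__(
            self,
            "equivalents",
            frozenset(tuple(e) for e in self.equivalents) - {self.expected},
        )

    @property
    def accepted(self) -> frozenset[tuple[str, str]]:
        return self.equivalents | {self.expected}


@dataclass(frozen=True)
class Prf:
    precision: float
    recall: float

    @property
    def f1(self) -> float:
        if self.precision + self.recall == 0:
            return 0.0
        return 2 * self.precision * self.recall / (self.precision + self.recall)

    def as_dict(self) -> dict[str, float]:
        return {"precision": self.precision, "recall": self.recall, "f1": self.f1}


@dataclass
class EvalResult:
    """Per-category and overall metrics under the top and any conditions."""

    overall: dict[str, Prf]  # {"top": Prf, "any": Prf}
    by_category: dict[str, dict[str, Prf]] = field(default_factory=dict)
    n_records: int = 0
    n_grounded: int = 0
    n_disambiguated: int = 0

    def as_dict(self) -> dict:
        return {
            "overall": {k: v.as_dict() for k, v in self.overall.items()},
            "by_category": {
                cat: {k: v.as_dict() for k, v in conds.items()}
                for cat, conds in sorted(self.by_category.items())
            },
            "n_records": self.n_records,
            "n_grounded": self.n_grounded,
            "n_disambiguated": self.n_disambiguated,
        }


def _prf(hits: int, grounded: int, total: int) -> Prf:
    return Prf(
        precision=hits / grounded if grounded else 0.0,
        recall=hits / total if total else 0.0,
    )


def evaluate(
    grounder: Grounder,
    records: Sequence[EvalRecord],
    organisms: Sequence[str] | None = None,
) -> EvalResult:
    """Run the grounder over the records and score both conditions."""
    if not records:
        raise ValueError("cannot evaluate an empty record list")
    tallies: dict[str | None, dict[str, int]] = {}

    def tally(cat: str | None) -> dict[str, int]:
        return tallies.setdefault(
            cat, {"total": 0, "grounded": 0, "top": 0, "any": 0}
        )

    n_disamb = 0
    for record in records:
        matches = grounder.ground(
            record.entity_text, context=record.context, organisms=organisms
        )
        if (
            record.context is not None
            and grounder.models is not None
            and grounder.models.get(canonicalize(record.entity_text)) is not None
        ):
            n_disamb += 1
        hit_top = bool(matches) and matches[0].entity in record.accepted
        hit_any = any(m.entity in record.accepted for m in matches)
        buckets: list[str | None] = [None]
        if record.category is not None:
            buckets.append(record.category)
        for cat in buckets:
            t = tally(cat)
            t["total"] += 1
            if matches:
                t["grounded"] += 1
            if hit_top:
                t["top"] += 1
            if hit_any:
                t["any"] += 1

    overall_t = tallies[None]
    overall = {
        "top": _prf(overall_t["top"], overall_t["grounded"], overall_t["total"]),
        "any": _prf(overall_t["any"], overall_t["grounded"], overall_t["total"]),
    }
    by_category = {
        cat: {
            "top": _prf(t["top"], t["grounded"], t["total"]),
            "any": _prf(t["any"], t["grounded"], t["total"]),
        }
        for cat, t in tallies.items()
        if cat is not None
    }
    return EvalResult(
        overall=overall,
        by_category=by_category,
        n_records=overall_t["total"],
        n_grounded=overall_t["grounded"],
        n_disambiguated=n_disamb,
    )


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def load_eval_records_jsonl(path: str | Path) -> list[EvalRecord]:
    """Load records from JSONL with keys entity_text, expected,
    optionally context, category, equivalents."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                records.append(
                    EvalRecord(
                        entity_text=rec["entity_text"],
                        expected=tuple(rec["expected"]),
                        context=rec.get("context"),
                        category=rec.get("category"),
                        equivalents=frozenset(
                            tuple(e) for e in rec.get("equivalents", [])
                        ),
                    )
                )
            except (KeyError, ValueError, TypeError) as err:
                raise ValueError(f"{path}:{lineno}: malformed record: {err}") from None
    return records


def load_equivalences(path: str | Path) -> dict[tuple[str, str], set[tuple[str, str]]]:
    """Load a symmetric equivalence map from 2-column TSV of
    ``namespace:identifier`` pairs."""
    mapping: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        try:
            left, right = line.split("\t")
            a = tuple(left.split(":", 1))
            b = tuple(right.split(":", 1))
            if len(a) != 2 or len(b) != 2:
                raise ValueError
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: expected two tab-separated ns:id pairs"
            ) from None
        mapping.setdefault(a, set()).add(b)
        mapping.setdefault(b, set()).add(a)
    return mapping


def apply_equivalences(
    records: Sequence[EvalRecord],
    mapping: Mapping[tuple[str, str], set[tuple[str, str]]],
) -> list[EvalRecord]:
    """Extend each record's accepted set with mapped equivalents."""
    out = []
    for record in records:
        extra = mapping.get(record.expected, set())
        out.append(
            EvalRecord(
                entity_text=record.entity_text,
                expected=record.expected,
                context=record.context,
                category=record.category,
                equivalents=record.equivalents | frozenset(extra),
            )
        )
    return out
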