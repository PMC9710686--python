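"""Scoring constants.

The match score is a product of a string-similarity component and a
term-status component, both in (0, 1].  The constants live in the
packaged ``scoring.json`` file so that a deployment can swap them out;
``load_scoring_config`` accepts an alternative path.

The shipped constants satisfy the ordering requirements of the scoring
model (see :mod:`bioground.stringmatch`): an exact match of a standard
name scores exactly 1.0; status ranks standard_name > curated > synonym
> former_name; every feature penalty strictly decreases the score; and
status differences dominate small string-similarity differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = ["ScoringConfig", "load_scoring_config", "DEFAULT_SCORING"]


@dataclass(frozen=True)
class ScoringConfig:
    """Multiplicative scoring constants.

    status_multipliers
        One factor per term status; standard_name must be 1.0 so the
        exact-standard-name anchor holds.
    penalties
        One factor per string-comparison feature, each in (0, 1).
    """

    status_multipliers: dict[str, float] = field(default_factory=dict)
    penalties: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.status_multipliers.items():
            if not 0.0 < value <= 1.0:
                raise ValueError(f"status multiplier {name}={value} outside (0, 1]")
        if self.status_multipliers.get("standard_name") != 1.0:
            raise ValueError("standard_name multiplier must be exactly 1.0")
        for name, value in self.penalties.items():
            if not 0.0 < value < 1.0:
                raise ValueError(f"penalty {name}={value} outside (0, 1)")


def load_scoring_config(path: str | Path | None = None) -> ScoringConfig:
    """Load scoring constants from ``path`` or the packaged defaults."""
    if path is None:
        ref = resources.files("bioground.data").joinpath("scoring.json")
        with ref.open("r", encoding="utf-8") as fh:
            raw = json.load(fh)
    else:
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
    return ScoringConfig(
        status_multipliers=dict(raw["status_multipliers"]),
        penalties=dict(raw["penalties"]),
    )


DEFAULT_SCORING: ScoringConfig = load_scoring_config()
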