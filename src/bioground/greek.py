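"""Greek-letter tables used by variant generation.

Biomedical nomenclature writes Greek elements three ways: spelled out
("delta"), as the Greek letter ("δ"), or contracted to a single Latin
initial ("d", as in PKCD).  The tables here map between the three forms
for the 24 letters of the Greek alphabet; the packaged ``greek.json``
data file is the single source of truth.
"""

from __future__ import annotations

import json
from importlib import resources

__all__ = [
    "GREEK_NAME_TO_LETTER",
    "GREEK_LETTER_TO_NAME",
    "GREEK_NAME_TO_INITIAL",
]


def _load_table() -> dict[str, str]:
    ref = resources.files("bioground.data").joinpath("greek.json")
    with ref.open("r", encoding="utf-8") as fh:
        return json.load(fh)


#: spelled-out name (lowercase) -> Greek letter, e.g. "delta" -> "δ"
GREEK_NAME_TO_LETTER: dict[str, str] = _load_table()

#: Greek letter -> spelled-out name, e.g. "δ" -> "delta"
GREEK_LETTER_TO_NAME: dict[str, str] = {
    v: k for k, v in GREEK_NAME_TO_LETTER.items()
}

#: spelled-out name -> single Latin initial, e.g. "delta" -> "d"
GREEK_NAME_TO_INITIAL: dict[str, str] = {
    k: k[0] for k in GREEK_NAME_TO_LETTER
}
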