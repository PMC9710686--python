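"""Species-priority reranking of gene/protein matches.

Orthologous genes in different organisms often share synonyms, and a
lexicon covering several species returns equally scored matches for all
of them.  An ordered organism priority list (NCBI taxonomy ids, highest
priority first) breaks those ties: among matches whose scores are equal
within a tolerance, organisms earlier in the list come first.  Scores
are never changed and strictly different scores are never reordered —
the priority expresses a preference, not evidence.

A priority list can also be derived from the MeSH annotations of the
publication the text came from, via a packaged MeSH-descriptor ->
taxonomy-id table covering common model organisms.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .stringmatch import ScoredMatch

__all__ = [
    "SpeciesPriority",
    "rerank_by_species",
    "priority_from_mesh",
    "load_mesh_taxonomy",
]

#: scores closer than this are considered tied for reranking purposes
SCORE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class SpeciesPriority:
    """Ordered organism (taxonomy id) preference, highest first."""

    organisms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "organisms", tuple(str(o) for o in self.organisms)
        )
        if len(set(self.organisms)) != len(self.organisms):
            raise ValueError("species priority list contains duplicates")

    def rank(self, organism: str | None) -> int:
        """Priority rank; organisms not listed (or absent) rank last."""
        if organism is not None and organism in self.organisms:
            return self.organisms.index(organism)
        return len(self.organisms)

    def __bool__(self) -> bool:
        return bool(self.organisms)

    def __iter__(self):
        return iter(self.organisms)


def rerank_by_species(
    matches: Sequence[ScoredMatch],
    priority: SpeciesPriority,
    tolerance: float = SCORE_TOLERANCE,
) -> list[ScoredMatch]:
    """Reorder tied matches by organism priority.

    ``matches`` must already be sorted by descending score.  Runs of
    matches whose scores are within ``tolerance`` of each other are
    stably re-sorted by priority rank, so matches without an organism
    annotation (and organisms not in the list) keep their relative
    order.  The result is a permutation of the input with untouched
    scores, and the operation is idempotent.
    """
    if not priority:
        return list(matches)
    out: list[ScoredMatch] = []
    i = 0
    n = len(matches)
    while i < n:
        j = i + 1
        while j < n and abs(matches[j].score - matches[i].score) <= tolerance:
            j += 1
        group = list(matches[i:j])
        group.sort(key=lambda m: priority.rank(m.term.organism))
        out.extend(group)
        i = j
    return out


def load_mesh_taxonomy(path: str | Path | None = None) -> dict[str, str]:
    """Load the MeSH-descriptor -> taxonomy-id table (2-column TSV)."""
    if path is None:
        ref = resources.files("bioground.data").joinpath("mesh_taxonomy.tsv")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        mesh_id, taxon = line.split("\t")
        mapping[mesh_id] = taxon
    return mapping


def priority_from_mesh(
    mesh_terms: Sequence[str],
    mesh_to_taxon: Mapping[str, str] | None = None,
) -> SpeciesPriority:
    """Derive a species priority from a publication's MeSH annotations.

    Organisms appear in first-occurrence order of their MeSH
    descriptors; descriptors without a taxonomy mapping are skipped.
    """
    mapping = load_mesh_taxonomy() if mesh_to_taxon is None else mesh_to_taxon
    organisms: list[str] = []
    for mesh_id in mesh_terms:
        taxon = mapping.get(mesh_id)
        if taxon is not None and taxon not in organisms:
            organisms.append(taxon)
    return SpeciesPriority(tuple(organisms))
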