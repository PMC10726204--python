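"""Feature rankings and named feature subsets with provenance.

These are the currency of the integrated feature-selection pipeline:
each ranking method produces a :class:`FeatureRanking`, thresholding
turns a ranking into a :class:`FeatureSubset`, and set combination /
recursive elimination transform subsets while accumulating a provenance
trail that records how the subset was obtained.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .vegindex import index_order, list_indices

__all__ = ["FeatureRanking", "FeatureSubset"]


def _table_sorted(names: Iterable[str]) -> list[str]:
    """Sort names by canonical table order; unknown names go last, alphabetically."""
    known = set(list_indices())

    def key(n: str):
        return (0, index_order(n)) if n in known else (1, n)

    return sorted(names, key=key)


@dataclasses.dataclass(frozen=True)
class FeatureRanking:
    """Ordered (name, score) list from one ranking method.

    Sorted by score descending; ties broken by canonical table order so
    rankings are reproducible.
    """

    method: str
    scores: tuple[tuple[str, float], ...]

    @classmethod
    def from_scores(cls, method: str, scores: Mapping[str, float]) -> "FeatureRanking":
        names = list(scores)
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in ranking")
        for n, s in scores.items():
            if not (s == s and abs(s) != float("inf")):
                raise ValueError(f"non-finite score for {n!r}: {s!r}")
        ordered = sorted(
            names, key=lambda n: (-float(scores[n]), _order_key(n))
        )
        return cls(method=method, scores=tuple((n, float(scores[n])) for n in ordered))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.scores]

    def as_dict(self) -> dict[str, float]:
        return dict(self.scores)

    def score_of(self, name: str) -> float:
        return dict(self.scores)[name]

    def to_json(self) -> dict:
        return {"method": self.method, "scores": [[n, s] for n, s in self.scores]}


def _order_key(n: str):
    known = set(list_indices())
    return (0, index_order(n)) if n in known else (1, n)


@dataclasses.dataclass(frozen=True)
class FeatureSubset:
    """A named subset of the index library plus how it came to be.

    ``names`` is kept in canonical table order; ``provenance`` is a
    non-empty tuple of records (method, threshold, combination mode,
    elimination trace, ...) accumulated by each selection step.
    """

    names: tuple[str, ...]
    provenance: tuple[dict, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate names in subset")
        if not self.provenance:
            raise ValueError("provenance must be non-empty")

    @classmethod
    def create(cls, names: Iterable[str], provenance: Sequence[dict]) -> "FeatureSubset":
        return cls(names=tuple(_table_sorted(set(names))), provenance=tuple(provenance))

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.names)

    def to_json(self) -> dict:
        return {"retained": list(self.names), "provenance": list(self.provenance)}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2, default=str) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FeatureSubset":
        d = json.loads(Path(path).read_text())
        return cls.create(d["retained"], d["provenance"])
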