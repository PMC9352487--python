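"""Evaluation index system: definitions, validation, and YAML/JSON I/O.

A psychological evaluation index system is an ordered collection of
aggregate indices (e.g. anxiety, depression, sleep quality).  Each index
``j`` carries a full score :math:`E_j` and four strictly increasing
grey-class boundary points :math:`a_1 < a_2 < a_3 < a_4` that delimit the
three severity intervals ``[a_1, a_2]`` (good), ``[a_2, a_3]`` (ordinary)
and ``[a_3, a_4]`` (morbid).  Index weights are score proportions
:math:`Z_j = E_j / \\sum_j E_j`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigurationError",
    "IndexDefinition",
    "IndexSystem",
    "load_index_system",
    "save_index_system",
    "default_index_system",
]


class ConfigurationError(ValueError):
    """Raised when an index-system configuration violates its invariants."""


@dataclass(frozen=True)
class IndexDefinition:
    """One evaluation index: a name, its full score and class boundaries."""

    name: str
    full_score: float
    boundaries: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("index name must be non-empty")
        if len(self.boundaries) != 4:
            raise ConfigurationError(
                f"index {self.name!r}: exactly four boundaries required, "
                f"got {len(self.boundaries)}"
            )
        b = tuple(float(v) for v in self.boundaries)
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "full_score", float(self.full_score))
        if not all(np.isfinite(b)):
            raise ConfigurationError(f"index {self.name!r}: non-finite boundary")
        if not (b[0] < b[1] < b[2] < b[3]):
            raise ConfigurationError(
                f"index {self.name!r}: boundaries must be strictly increasing, "
                f"got {b}"
            )
        if self.full_score <= 0:
            raise ConfigurationError(
                f"index {self.name!r}: full score must be positive, "
                f"got {self.full_score}"
            )
        if b[3] > self.full_score:
            raise ConfigurationError(
                f"index {self.name!r}: upper boundary {b[3]} exceeds full "
                f"score {self.full_score}"
            )

    @property
    def centers(self) -> tuple[float, float, float]:
        """Class centers: midpoints of consecutive boundary pairs."""
        b = self.boundaries
        return tuple((b[k] + b[k + 1]) / 2.0 for k in range(3))


@dataclass(frozen=True)
class IndexSystem:
    """Ordered, validated collection of indices with derived weights."""

    indices: tuple[IndexDefinition, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(self.indices))
        if not self.indices:
            raise ConfigurationError("index system must contain at least one index")
        names = [ix.name for ix in self.indices]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigurationError(f"duplicate index names: {sorted(dupes)}")

    @property
    def names(self) -> list[str]:
        return [ix.name for ix in self.indices]

    @property
    def total(self) -> float:
        """Total = sum of full scores over all indices."""
        return float(sum(ix.full_score for ix in self.indices))

    @property
    def weights(self) -> np.ndarray:
        """Score-proportion weights Z_j = E_j / Total; they sum to 1."""
        scores = np.array([ix.full_score for ix in self.indices], dtype=float)
        return scores / scores.sum()

    @property
    def center_matrix(self) -> np.ndarray:
        """(n_indices, 3) array of class centers."""
        return np.array([ix.centers for ix in self.indices], dtype=float)

    @property
    def full_scores(self) -> np.ndarray:
        return np.array([ix.full_score for ix in self.indices], dtype=float)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self) -> Iterable[IndexDefinition]:
        return iter(self.indices)

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "indices": [
                {
                    "name": ix.name,
                    "full_score": ix.full_score,
                    "boundaries": list(ix.boundaries),
                }
                for ix in self.indices
            ],
        }


def _system_from_dict(payload: dict, source: str) -> IndexSystem:
    if not isinstance(payload, dict) or "indices" not in payload:
        raise ConfigurationError(f"{source}: expected a mapping with an 'indices' list")
    entries = payload["indices"]
    if not isinstance(entries, list):
        raise ConfigurationError(f"{source}: 'indices' must be a list")
    indices = []
    for i, entry in enumerate(entries):
        try:
            indices.append(
                IndexDefinition(
                    name=entry["name"],
                    full_score=entry["full_score"],
                    boundaries=tuple(entry["boundaries"]),
                )
            )
        except KeyError as exc:
            raise ConfigurationError(
                f"{source}: entry {i} missing required key {exc}"
            ) from exc
    return IndexSystem(tuple(indices))


def load_index_system(path: str | Path) -> IndexSystem:
    """Load and validate an index system from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"index configuration not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    return _system_from_dict(payload, str(path))


def save_index_system(system: IndexSystem, path: str | Path) -> None:
    """Serialize a validated index system to YAML or JSON."""
    path = Path(path)
    payload = system.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def default_index_system() -> IndexSystem:
    """The packaged six-index evaluation system.

    Six aggregate indices with full scores (40, 40, 30, 30, 30, 30),
    Total = 200.  Boundaries sit at (0.2, 0.4, 0.6, 0.8) of each full
    score, so every index's ordinary-class center is half its full score
    and the 100-point overall-score threshold coincides with the
    all-indices-at-ordinary-center configuration.
    """
    ref = resources.files("greypsy.data").joinpath("default_indices.yaml")
    payload = yaml.safe_load(ref.read_text())
    return _system_from_dict(payload, "default_indices.yaml")
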