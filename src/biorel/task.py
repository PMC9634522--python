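"""Task configurations: relation categories, entity types, and the
type-constraint ("regulation") rules declaring which (type, type,
category) triples are legal.

Both shared-task-style configurations ship as editable YAML under
``biorel/data/``; ``load_task("bbrel")`` etc. loads them by name.
Constraint triples are unordered in the entity positions — the tasks do
not model relation direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class ConstraintRule:
    """A task's category inventory and legal type-pair constraints.

    ``legal_triples`` of ``None`` means the task is unconstrained (every
    type pair may carry every category).  ``orientation_priority`` lists
    entity types that should come first on oriented dependency paths and
    in role-named relation output (empty list = sentence order).
    """

    name: str
    categories: list[str]
    entity_types: list[str]
    legal_triples: Optional[set[tuple[str, str, str]]] = None
    orientation_priority: list[str] = field(default_factory=list)
    roles: dict[str, list[str]] = field(default_factory=dict)
    clusters: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.categories.count("none") != 1:
            raise ValueError("category list must contain 'none' exactly once")
        if self.legal_triples is not None:
            canon = set()
            for a, b, r in self.legal_triples:
                canon.add((min(a, b), max(a, b), r))
            self.legal_triples = canon

    @property
    def positive_categories(self) -> list[str]:
        return [c for c in self.categories if c != "none"]

    def pair_is_legal(self, type_a: str, type_b: str) -> bool:
        if self.legal_triples is None:
            return True
        a, b = min(type_a, type_b), max(type_a, type_b)
        return any(t[0] == a and t[1] == b for t in self.legal_triples)

    def triple_is_legal(self, type_a: str, type_b: str, category: str) -> bool:
        if self.legal_triples is None:
            return True
        a, b = min(type_a, type_b), max(type_a, type_b)
        return (a, b, category) in self.legal_triples


def _from_dict(d: dict) -> ConstraintRule:
    triples = d.get("legal_triples")
    return ConstraintRule(
        name=d["name"],
        categories=list(d["categories"]),
        entity_types=list(d["entity_types"]),
        legal_triples=None if triples is None else {tuple(t) for t in triples},
        orientation_priority=list(d.get("orientation_priority", [])),
        roles={k: list(v) for k, v in (d.get("roles") or {}).items()},
        clusters={k: list(v or []) for k, v in (d.get("clusters") or {}).items()},
    )


def load_task(name_or_path: str) -> ConstraintRule:
    """Load a task config by bundled name ('bbrel', 'seedev') or file path."""
    p = Path(name_or_path)
    if p.suffix in (".yaml", ".yml") and p.exists():
        return _from_dict(yaml.safe_load(p.read_text()))
    ref = resources.files("biorel.data") / f"{name_or_path}.yaml"
    return _from_dict(yaml.safe_load(ref.read_text()))
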