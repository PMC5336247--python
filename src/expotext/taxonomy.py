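"""Exposure-information taxonomy: a 32-node, two-branch label hierarchy.

The taxonomy categorises human chemical-exposure information under two main
branches: *biomonitoring* (exposure and effect biomarkers, subdivided by
biological matrix or marker character) and *exposure routes* (oral intake,
inhalation, dermal and combined exposure, subdivided by source).  Labels are
hierarchical: an abstract annotated with a sub-node (e.g. ``Food``) counts as
positive for every ancestor (``Oral intake``, ``EXPOSURE ROUTES``) when node
classifiers are trained — the upward closure implemented by
:func:`propagate_labels`.

Nodes have a canonical ASCII slug (``hair_nail``) and a display name
(``Hair/nail``); all lookup functions accept either.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TaxonomyError",
    "TaxonomyNode",
    "Taxonomy",
    "load_taxonomy",
    "default_taxonomy",
    "propagate_labels",
]


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy descriptions or unknown node lookups."""


@dataclass(frozen=True)
class TaxonomyNode:
    """A single taxonomy node.

    Attributes
    ----------
    name : str
        Canonical slug, unique within the taxonomy.
    display : str
        Human-readable label as printed in reports.
    parent : str | None
        Slug of the parent node, or ``None`` for a branch root.
    children : tuple[str, ...]
        Slugs of direct children, in insertion order.
    """

    name: str
    display: str
    parent: str | None = None
    children: tuple[str, ...] = field(default_factory=tuple)


# (slug, display, parent-slug) rows of the default exposure taxonomy.
# Two branches: biomonitoring and exposure routes; 32 nodes in total.
_DEFAULT_ROWS: tuple[tuple[str, str, str | None], ...] = (
    ("biomonitoring", "BIOMONITORING", None),
    ("exposure_biomarker", "Exposure biomarker", "biomonitoring"),
    ("adipose_tissue", "Adipose tissue", "exposure_biomarker"),
    ("blood", "Blood", "exposure_biomarker"),
    ("hair_nail", "Hair/nail", "exposure_biomarker"),
    ("mothers_milk", "Mother's milk", "exposure_biomarker"),
    ("other_tissue", "Other tissue", "exposure_biomarker"),
    ("placenta", "Placenta", "exposure_biomarker"),
    ("urine", "Urine", "exposure_biomarker"),
    ("effect_biomarker", "Effect biomarker", "biomonitoring"),
    ("biomarker", "Biomarker", "effect_biomarker"),
    ("gene", "Gene", "biomarker"),
    ("molecule", "Molecule", "biomarker"),
    ("lipid", "Lipid", "molecule"),
    ("other_molecule", "Other molecule", "molecule"),
    ("protein", "Protein", "molecule"),
    ("other_effect_biomarker", "Other effect biomarker", "biomarker"),
    ("oxidative_stress_marker", "Oxidative stress marker", "biomarker"),
    ("physiological_parameter", "Physiological parameter", "effect_biomarker"),
    ("exposure_routes", "EXPOSURE ROUTES", None),
    ("combined", "Combined", "exposure_routes"),
    ("dermal_exposure", "Dermal exposure", "exposure_routes"),
    ("inhalation", "Inhalation", "exposure_routes"),
    ("outdoor_air", "Outdoor air", "inhalation"),
    ("indoor_air", "Indoor air", "inhalation"),
    ("personal_air", "Personal air", "inhalation"),
    ("oral_intake", "Oral intake", "exposure_routes"),
    ("drinking_water", "Drinking water", "oral_intake"),
    ("dust", "Dust", "oral_intake"),
    ("food", "Food", "oral_intake"),
    ("products", "Products", "oral_intake"),
    ("soil", "Soil", "oral_intake"),
)


def _slugify(name: str) -> str:
    out = []
    for ch in name.strip().lower():
        if ch.isalnum() or ch == "_":
            out.append(ch)
        elif ch in " /-":
            out.append("_")
        # apostrophes and other punctuation are dropped
    slug = "".join(out)
    while "__" in slug:
        slug = slug.replace("__", "_")
    return slug.strip("_")


class Taxonomy:
    """A forest of :class:`TaxonomyNode` objects with hierarchy queries.

    Iteration and :attr:`node_names` follow depth-first pre-order over the
    branch roots, which is the traversal order used by every report.
    """

    def __init__(self, nodes: Sequence[TaxonomyNode]):
        self._nodes: dict[str, TaxonomyNode] = {}
        self._by_display: dict[str, str] = {}
        for node in nodes:
            if node.name in self._nodes:
                raise TaxonomyError(f"duplicate node name: {node.name!r}")
            self._nodes[node.name] = node
            self._by_display[node.display.lower()] = node.name
        self._validate()
        self.roots: tuple[str, ...] = tuple(
            n.name for n in nodes if n.parent is None
        )
        self._order: tuple[str, ...] = tuple(self._preorder())

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        for node in self._nodes.values():
            if node.parent is not None and node.parent not in self._nodes:
                raise TaxonomyError(
                    f"node {node.name!r} has unknown parent {node.parent!r}"
                )
        # cycle check: walk parents, must terminate within |nodes| steps
        for name in self._nodes:
            seen = {name}
            cur = self._nodes[name].parent
            while cur is not None:
                if cur in seen:
                    raise TaxonomyError(f"cycle detected at node {name!r}")
                seen.add(cur)
                cur = self._nodes[cur].parent

    def _preorder(self) -> Iterable[str]:
        def walk(name: str) -> Iterable[str]:
            yield name
            for child in self._nodes[name].children:
                yield from walk(child)

        for root in self.roots:
            yield from walk(root)

    # -- lookups --------------------------------------------------------

    def resolve(self, name: str) -> str:
        """Return the canonical slug for a slug or display name."""
        if name in self._nodes:
            return name
        key = name.lower()
        if key in self._by_display:
            return self._by_display[key]
        slug = _slugify(name)
        if slug in self._nodes:
            return slug
        raise TaxonomyError(f"unknown taxonomy node: {name!r}")

    def __contains__(self, name: str) -> bool:
        try:
            self.resolve(name)
            return True
        except TaxonomyError:
            return False

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterable[str]:
        return iter(self._order)

    @property
    def node_names(self) -> tuple[str, ...]:
        return self._order

    def node(self, name: str) -> TaxonomyNode:
        return self._nodes[self.resolve(name)]

    def display(self, name: str) -> str:
        return self.node(name).display

    def depth(self, name: str) -> int:
        return len(self.ancestors(name))

    def leaves(self) -> tuple[str, ...]:
        return tuple(n for n in self._order if not self._nodes[n].children)

    # -- hierarchy queries ----------------------------------------------

    def ancestors(self, name: str) -> list[str]:
        """Strict ancestors of *name*, ordered parent-first up to the root."""
        out: list[str] = []
        cur = self._nodes[self.resolve(name)].parent
        while cur is not None:
            out.append(cur)
            cur = self._nodes[cur].parent
        return out

    def descendants(self, name: str) -> list[str]:
        """Strict descendants of *name* in pre-order."""
        out: list[str] = []

        def walk(n: str) -> None:
            for child in self._nodes[n].children:
                out.append(child)
                walk(child)

        walk(self.resolve(name))
        return out

    # -- serialization --------------------------------------------------

    def to_rows(self) -> list[dict[str, str | None]]:
        return [
            {
                "name": n,
                "display": self._nodes[n].display,
                "parent": self._nodes[n].parent,
            }
            for n in self._order
        ]

    def to_json(self) -> str:
        return json.dumps(self.to_rows(), indent=2) + "\n"


def _build(rows: Iterable[Mapping[str, object]]) -> Taxonomy:
    rows = list(rows)
    children: dict[str, list[str]] = {}
    slugs: list[tuple[str, str, str | None]] = []
    seen: set[str] = set()
    for row in rows:
        raw_name = str(row["name"])
        slug = row.get("slug") or (
            raw_name if raw_name == _slugify(raw_name) else _slugify(raw_name)
        )
        display = str(row.get("display") or row["name"])
        parent_raw = row.get("parent")
        parent = None if parent_raw in (None, "") else _slugify(str(parent_raw))
        if slug in seen:
            raise TaxonomyError(f"duplicate node name: {slug!r}")
        if parent == slug:
            raise TaxonomyError(f"cycle detected at node {slug!r}")
        seen.add(slug)
        slugs.append((str(slug), display, parent))
    for slug, _display, parent in slugs:
        if parent is not None:
            children.setdefault(parent, []).append(slug)
    nodes = [
        TaxonomyNode(slug, display, parent, tuple(children.get(slug, ())))
        for slug, display, parent in slugs
    ]
    return Taxonomy(nodes)


def default_taxonomy() -> Taxonomy:
    """The built-in 32-node exposure taxonomy (two-branch forest)."""
    return _build(
        {"name": s, "display": d, "parent": p} for s, d, p in _DEFAULT_ROWS
    )


def load_taxonomy(source: object = "builtin") -> Taxonomy:
    """Load a taxonomy.

    Parameters
    ----------
    source : "builtin" | path | list of mappings
        ``"builtin"`` (default) returns :func:`default_taxonomy`.  A path to a
        JSON or YAML file, or an in-memory list of ``{"name", "parent"}``
        mappings, builds a custom taxonomy (names are slugified; an optional
        ``display`` key preserves the printable label).
    """
    if source == "builtin" or source is None:
        return default_taxonomy()
    if isinstance(source, (list, tuple)):
        return _build(source)
    # path-like
    import os

    path = os.fspath(source)  # type: ignore[arg-type]
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if path.endswith((".yaml", ".yml")):
        import yaml

        rows = yaml.safe_load(text)
    else:
        rows = json.loads(text)
    if not isinstance(rows, list):
        raise TaxonomyError("taxonomy description must be a list of nodes")
    return _build(rows)


def propagate_labels(taxonomy: Taxonomy, labels: Iterable[str]) -> set[str]:
    """Upward closure of a label set: the labels plus all their ancestors.

    Sub-node annotations count as positives for every ancestor node, so the
    closure of ``{"food"}`` is ``{"food", "oral_intake", "exposure_routes"}``.
    Idempotent and monotone in the input set.
    """
    out: set[str] = set()
    for label in labels:
        slug = taxonomy.resolve(label)
        out.add(slug)
        out.update(taxonomy.ancestors(slug))
    return out
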