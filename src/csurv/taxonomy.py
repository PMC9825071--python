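"""Four-level cohort-data taxonomy: themes > domains > families > objects.

The data model organises every variable a cohort collects into a simple
acyclic tree exactly four levels deep.  Level 1 ("theme") groups data by
common usage or modality (e.g. Cognitive status, Imaging); level 2 ("domain")
and level 3 ("family") progressively narrow the construct; level 4 ("object")
is a single measured variable.  The tree supports both grouped selection
("all processing speed variables") and individual variable selection, which
is the granularity most data-access committees work at.

Documents are plain YAML (JSON parses too): a ``version`` string and an
ordered list of themes, each node a map with ``index``, ``label`` and
``children``.  A formal JSON-Schema for the layout ships in
``csurv/schemas/taxonomy.schema.json``; the richer invariants (leaf rule,
sibling uniqueness, level nesting) are enforced here at load time.

Two reference documents ship with the package:

``reference_taxonomy.yaml``
    all 18 theme slots; themes whose content is not part of the harmonised
    reference subset are stubs flagged ``provisional: true``.
``table1_taxonomy.yaml``
    the fully specified 32-object harmonised subset only.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Sequence

import yaml

from .errors import (
    AmbiguousPathError,
    DuplicateLabelError,
    PathNotFoundError,
    TaxonomyParseError,
    TaxonomyStructureError,
)

__all__ = [
    "LEVEL_NAMES",
    "TaxonomyNode",
    "Taxonomy",
    "NodePath",
    "load_taxonomy",
    "dump_taxonomy",
    "count_nodes",
    "resolve_path",
    "list_objects",
    "reference_taxonomy",
    "table1_taxonomy",
]

LEVEL_NAMES = {1: "theme", 2: "domain", 3: "family", 4: "object"}

#: A path of labels from the theme level downward; may stop at any level.
#: The empty path addresses the (implicit) root.
NodePath = tuple[str, ...]


def _norm_label(label: str) -> str:
    """Case-insensitive, whitespace-normalised comparison key."""
    return " ".join(label.split()).casefold()


@dataclass
class TaxonomyNode:
    """One node of the hierarchy.

    ``index`` is the ordinal within the parent; for themes it is the printed
    theme number (which is why theme indices are not necessarily contiguous).
    ``object_label`` is the human-readable variable label and is present
    exactly on level-4 nodes.  ``provisional`` marks placeholder nodes whose
    label or content is not yet settled; provisional non-leaf nodes are the
    only nodes allowed to be childless.
    """

    level: int
    index: int
    label: str
    children: list["TaxonomyNode"] = field(default_factory=list)
    object_label: str | None = None
    provisional: bool = False

    def is_leaf(self) -> bool:
        return not self.children

    def child(self, label: str) -> "TaxonomyNode | None":
        key = _norm_label(label)
        for node in self.children:
            if _norm_label(node.label) == key:
                return node
        return None

    def walk(self) -> Iterator["TaxonomyNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Taxonomy:
    """A validated four-level taxonomy: an ordered forest of themes."""

    version: str
    themes: list[TaxonomyNode] = field(default_factory=list)

    # -- queries -----------------------------------------------------------

    def walk(self) -> Iterator[TaxonomyNode]:
        for theme in self.themes:
            yield from theme.walk()

    def count_nodes(self, level: int) -> int:
        if level not in LEVEL_NAMES:
            raise ValueError(f"level must be in 1..4, got {level!r}")
        return sum(1 for node in self.walk() if node.level == level)

    def resolve(self, path: Sequence[str]) -> TaxonomyNode:
        return resolve_path(self, tuple(path))

    def objects(self, under: Sequence[str] = ()) -> list[tuple[NodePath, TaxonomyNode]]:
        return list_objects(self, tuple(under))

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {"version": self.version, "themes": [_node_to_dict(t) for t in self.themes]}

    def dumps(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)


def _node_to_dict(node: TaxonomyNode) -> dict[str, Any]:
    out: dict[str, Any] = {"index": node.index, "label": node.label}
    if node.provisional:
        out["provisional"] = True
    if node.level == 4:
        if node.object_label is not None and node.object_label != node.label:
            out["object_label"] = node.object_label
    else:
        out["children"] = [_node_to_dict(c) for c in node.children]
    return out


# ---------------------------------------------------------------------------
# loading & validation
# ---------------------------------------------------------------------------

def _build_node(raw: Any, level: int, parent_path: tuple[str, ...], ordinal: int) -> TaxonomyNode:
    if not isinstance(raw, dict):
        raise TaxonomyParseError(
            f"node under {'/'.join(parent_path) or '<root>'} must be a mapping, got {type(raw).__name__}"
        )
    try:
        label = raw["label"]
    except KeyError:
        raise TaxonomyParseError(
            f"node under {'/'.join(parent_path) or '<root>'} is missing the 'label' key"
        ) from None
    if not isinstance(label, str) or not label.strip():
        raise TaxonomyParseError(
            f"label under {'/'.join(parent_path) or '<root>'} must be non-empty text"
        )
    path = parent_path + (label,)

    index = raw.get("index", ordinal)
    if not isinstance(index, int) or isinstance(index, bool) or index < 1:
        raise TaxonomyParseError(f"node {'/'.join(path)}: 'index' must be a positive integer")

    provisional = bool(raw.get("provisional", False))
    raw_children = raw.get("children", [])
    if raw_children is None:
        raw_children = []
    if not isinstance(raw_children, list):
        raise TaxonomyParseError(f"node {'/'.join(path)}: 'children' must be a list")

    if level > 4:
        raise TaxonomyStructureError(
            f"node {'/'.join(path)}: nesting deeper than four levels (objects are leaves)"
        )
    if level == 4 and raw_children:
        raise TaxonomyStructureError(
            f"object node {'/'.join(path)} has children; level-4 nodes must be leaves"
        )

    children = [
        _build_node(child, level + 1, path, i + 1) for i, child in enumerate(raw_children)
    ]
    _check_sibling_labels(children, path)

    if level < 4 and not children and not provisional:
        raise TaxonomyStructureError(
            f"{LEVEL_NAMES[level]} node {'/'.join(path)} has no children; every leaf "
            f"must be a level-4 object (mark placeholder nodes 'provisional: true')"
        )

    object_label = raw.get("object_label") if level == 4 else None
    if level == 4 and object_label is None:
        object_label = label
    return TaxonomyNode(
        level=level,
        index=index,
        label=" ".join(label.split()),
        children=children,
        object_label=object_label,
        provisional=provisional,
    )


def _check_sibling_labels(nodes: list[TaxonomyNode], parent_path: tuple[str, ...]) -> None:
    seen: dict[str, str] = {}
    for node in nodes:
        key = _norm_label(node.label)
        if key in seen:
            raise DuplicateLabelError(
                f"duplicate sibling label {node.label!r} under "
                f"{'/'.join(parent_path) or '<root>'} (labels compare case-insensitively)"
            )
        seen[key] = node.label


def load_taxonomy(source: str | Path | io.TextIOBase | dict) -> Taxonomy:
    """Load and validate a taxonomy from YAML/JSON text, a file path, an open
    stream, or an already-parsed mapping.

    Raises :class:`TaxonomyParseError` for malformed documents,
    :class:`TaxonomyStructureError` for level-skipping / over-deep nesting /
    non-leaf objects, and :class:`DuplicateLabelError` for sibling clashes.
    """
    if isinstance(source, dict):
        doc = source
    else:
        if isinstance(source, Path):
            text = source.read_text(encoding="utf-8")
        elif isinstance(source, str):
            p = Path(source)
            # A path-looking short string that exists is read as a file.
            text = p.read_text(encoding="utf-8") if ("\n" not in source and p.is_file()) else source
        else:
            text = source.read()
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise TaxonomyParseError(f"malformed taxonomy document: {exc}") from exc
    if not isinstance(doc, dict):
        raise TaxonomyParseError("taxonomy document must be a mapping with 'version' and 'themes'")
    themes_raw = doc.get("themes")
    if not isinstance(themes_raw, list):
        raise TaxonomyParseError("taxonomy document is missing the 'themes' list")

    themes = [_build_node(raw, 1, (), i + 1) for i, raw in enumerate(themes_raw)]
    _check_sibling_labels(themes, ())
    indices = [t.index for t in themes]
    if len(set(indices)) != len(indices):
        dupes = sorted({i for i in indices if indices.count(i) > 1})
        raise TaxonomyStructureError(f"theme indices must be unique; repeated: {dupes}")
    return Taxonomy(version=str(doc.get("version", "0")), themes=themes)


def dump_taxonomy(taxonomy: Taxonomy, path: str | Path | None = None) -> str:
    """Serialise to canonical YAML; ``load_taxonomy(dump_taxonomy(T))`` is the
    identity on validated taxonomies."""
    text = taxonomy.dumps()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# queries (module-level functional surface)
# ---------------------------------------------------------------------------

def count_nodes(taxonomy: Taxonomy, level: int) -> int:
    """Number of nodes at ``level`` (1 themes .. 4 objects)."""
    return taxonomy.count_nodes(level)


def resolve_path(taxonomy: Taxonomy, path: Sequence[str]) -> TaxonomyNode:
    """Resolve a label path starting at the theme level to its unique node.

    Matching is case-insensitive and whitespace-normalised.  A failed match
    raises :class:`PathNotFoundError` carrying the labels available at the
    failing level.
    """
    path = tuple(path)
    if not path:
        raise PathNotFoundError("empty path does not address a node (it addresses the root)")
    if len(path) > 4:
        raise PathNotFoundError(f"path {path!r} is deeper than the four taxonomy levels")

    siblings = taxonomy.themes
    node: TaxonomyNode | None = None
    for depth, label in enumerate(path):
        key = _norm_label(label)
        matches = [n for n in siblings if _norm_label(n.label) == key]
        if not matches:
            nearest = tuple(n.label for n in siblings)
            raise PathNotFoundError(
                f"no {LEVEL_NAMES[depth + 1]} labelled {label!r} under "
                f"{'/'.join(path[:depth]) or '<root>'}; available: {', '.join(nearest) or '<none>'}",
                candidates=nearest,
            )
        if len(matches) > 1:  # pragma: no cover - sibling uniqueness forbids this
            raise AmbiguousPathError(f"label {label!r} matches {len(matches)} siblings")
        node = matches[0]
        siblings = node.children
    assert node is not None
    return node


def list_objects(
    taxonomy: Taxonomy, under: Sequence[str] = ()
) -> list[tuple[NodePath, TaxonomyNode]]:
    """All level-4 objects below a path, in document order, with their full
    four-label paths.  The empty path lists every object in the taxonomy."""
    under = tuple(under)
    if under:
        root = resolve_path(taxonomy, under)
        roots = [(tuple(under), root)]
    else:
        roots = [((theme.label,), theme) for theme in taxonomy.themes]

    out: list[tuple[NodePath, TaxonomyNode]] = []

    def descend(path: tuple[str, ...], node: TaxonomyNode) -> None:
        if node.level == 4:
            out.append((path, node))
            return
        for child in node.children:
            descend(path + (child.label,), child)

    for path, node in roots:
        descend(path, node)
    return out


# ---------------------------------------------------------------------------
# shipped reference documents
# ---------------------------------------------------------------------------

def _load_packaged(name: str) -> Taxonomy:
    text = resources.files("csurv.data").joinpath(name).read_text(encoding="utf-8")
    return load_taxonomy(text)


def reference_taxonomy() -> Taxonomy:
    """The full 18-theme reference taxonomy (harmonised subset + provisional
    theme stubs)."""
    return _load_packaged("reference_taxonomy.yaml")


def table1_taxonomy() -> Taxonomy:
    """The fully specified 32-object harmonised-variable subset."""
    return _load_packaged("table1_taxonomy.yaml")


def taxonomy_schema() -> dict:
    """The published JSON-Schema for taxonomy documents, as a dict."""
    text = resources.files("csurv.schemas").joinpath("taxonomy.schema.json").read_text(
        encoding="utf-8"
    )
    return json.loads(text)
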