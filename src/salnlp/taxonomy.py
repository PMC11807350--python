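"""Two-level data model of self-acknowledged limitation (SAL) types.

RCT limitation types are organized as 15 top-level categories (e.g.
``UnderpoweredStudy``, ``Population``), 11 of which are refined by a total
of 24 fine-grained sub-categories (e.g. ``SampleSize`` under
``UnderpoweredStudy``).  Sentences are labeled with sets of category names
at either granularity; at fine granularity top-level names remain valid
labels, because a sentence may acknowledge a limitation without enough
specificity for any sub-category.

The taxonomy ships as a versioned tab-separated data file inside the
package so that specialty extensions can be loaded from a user-supplied
path without code changes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "TopCategory",
    "FineCategory",
    "Taxonomy",
    "TaxonomyError",
    "UnknownLabelError",
    "load_taxonomy",
    "N_TOP",
    "N_FINE",
]

#: Cardinalities the bundled data model must satisfy.
N_TOP = 15
N_FINE = 24

_BUNDLED = "taxonomy_v1.tsv"


class TaxonomyError(ValueError):
    """The taxonomy definition violates a structural invariant."""


class UnknownLabelError(KeyError):
    """A label name does not exist at the requested granularity."""


@dataclass(frozen=True)
class TopCategory:
    name: str
    description: str
    children: tuple[str, ...] = ()


@dataclass(frozen=True)
class FineCategory:
    name: str
    parent: str
    description: str


@dataclass
class Taxonomy:
    """The full two-level SAL type structure with parent links."""

    tops: dict[str, TopCategory]
    fines: dict[str, FineCategory]
    version: str = "unknown"
    source: str = "bundled"
    _parent: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._parent = {f.name: f.parent for f in self.fines.values()}

    # -- label spaces -------------------------------------------------
    def top_names(self) -> list[str]:
        return list(self.tops)

    def fine_names(self) -> list[str]:
        return list(self.fines)

    def label_space(self, granularity: str) -> list[str]:
        """Ordered label names at a granularity.

        Fine granularity includes the top-level names as well, since
        sentences may carry only a top-level label.
        """
        if granularity == "top":
            return self.top_names()
        if granularity == "fine":
            return self.top_names() + self.fine_names()
        raise ValueError(f"granularity must be 'top' or 'fine', got {granularity!r}")

    # -- lookups ------------------------------------------------------
    def parent(self, fine_name: str) -> str:
        try:
            return self._parent[fine_name]
        except KeyError:
            raise UnknownLabelError(f"unknown fine-grained category: {fine_name!r}") from None

    def validate_label(self, name: str, granularity: str) -> bool:
        """True iff ``name`` exists at ``granularity`` (fine admits top names)."""
        if granularity == "top":
            return name in self.tops
        if granularity == "fine":
            return name in self.tops or name in self.fines
        raise ValueError(f"granularity must be 'top' or 'fine', got {granularity!r}")

    def coarsen(self, labels: Iterable[str]) -> frozenset[str]:
        """Replace every fine-grained label by its parent; merge duplicates.

        Top-level labels pass through unchanged.  Idempotent, never
        increases cardinality.
        """
        out: set[str] = set()
        for name in labels:
            if name in self.tops:
                out.add(name)
            elif name in self.fines:
                out.add(self._parent[name])
            else:
                raise UnknownLabelError(f"unknown category: {name!r}")
        return frozenset(out)


def _bundled_path() -> Path:
    return Path(str(resources.files("salnlp").joinpath("data").joinpath(_BUNDLED)))


def load_taxonomy(path: str | Path | None = None) -> Taxonomy:
    """Load the taxonomy from ``path`` or the bundled versioned file.

    Raises :class:`TaxonomyError` if the definition is corrupted: wrong
    cardinalities, duplicate names, a fine category naming a missing
    parent, or name collisions between the two levels.
    """
    src = Path(path) if path is not None else _bundled_path()
    version = "unknown"
    tops: dict[str, TopCategory] = {}
    fines: dict[str, FineCategory] = {}
    children: dict[str, list[str]] = {}
    with open(src, encoding="utf-8", newline="") as fh:
        rows = []
        for raw in fh:
            if raw.startswith("#"):
                if "version=" in raw:
                    version = raw.split("version=")[1].strip()
                continue
            rows.append(raw)
        reader = csv.DictReader(rows, delimiter="\t")
        for rec in reader:
            name = (rec.get("name") or "").strip()
            level = (rec.get("level") or "").strip()
            parent = (rec.get("parent") or "").strip()
            desc = (rec.get("description") or "").strip()
            if not name or level not in ("top", "fine"):
                raise TaxonomyError(f"malformed taxonomy record: {rec!r}")
            if name in tops or name in fines:
                raise TaxonomyError(f"duplicate category name: {name!r}")
            if level == "top":
                tops[name] = TopCategory(name=name, description=desc)
            else:
                if not parent:
                    raise TaxonomyError(f"fine category without parent: {name!r}")
                fines[name] = FineCategory(name=name, parent=parent, description=desc)
                children.setdefault(parent, []).append(name)

    for fine in fines.values():
        if fine.parent not in tops:
            raise TaxonomyError(
                f"fine category {fine.name!r} names unknown parent {fine.parent!r}"
            )
    # attach child lists
    for pname, kids in children.items():
        t = tops[pname]
        tops[pname] = TopCategory(name=t.name, description=t.description, children=tuple(kids))

    if len(tops) != N_TOP or len(fines) != N_FINE:
        raise TaxonomyError(
            f"expected {N_TOP} top-level and {N_FINE} fine-grained categories, "
            f"found {len(tops)} and {len(fines)} in {src}"
        )
    return Taxonomy(tops=tops, fines=fines, version=version, source=str(src))
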