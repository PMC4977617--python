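"""Trait/variable catalogue: the controlled vocabulary behind all encodings.

A catalogue lists, in a fixed order, every qualitative trait (descriptor) and
the alternate states ("variables") it may take. Each variable carries a global
integer code; the codes define the column order of the one-hot binary matrix
and of the phenoprint barcodes, so they are read from the catalogue file and
never re-derived. Monomorphic traits (a single allowed state) are legitimate
catalogue entries: polymorphism is a property of a panel, not of the
vocabulary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterator, Union

__all__ = [
    "VariableDef",
    "TraitDescriptor",
    "TraitCatalog",
    "CatalogError",
    "load_catalog",
    "save_catalog",
    "catalog_summary",
    "odisha_asg_catalog",
]

PathLike = Union[str, Path]


class CatalogError(ValueError):
    """Raised when a catalogue file violates its structural invariants."""


@dataclass(frozen=True)
class VariableDef:
    """One alternate state of a trait, with its global column code."""

    code: int
    label: str
    trait_key: str

    def __post_init__(self) -> None:
        if self.code < 1:
            raise CatalogError(f"variable code must be >= 1, got {self.code}")
        if not self.label:
            raise CatalogError(f"empty variable label for trait {self.trait_key!r}")


@dataclass(frozen=True)
class TraitDescriptor:
    """A qualitative trait and its ordered allowed states."""

    key: str
    name: str
    variables: tuple[VariableDef, ...]

    def __post_init__(self) -> None:
        if not self.variables:
            raise CatalogError(f"trait {self.key!r} has no variables")
        labels = [v.label for v in self.variables]
        if len(set(labels)) != len(labels):
            dup = next(l for l in labels if labels.count(l) > 1)
            raise CatalogError(f"duplicate variable label {dup!r} in trait {self.key!r}")

    @property
    def n_states(self) -> int:
        return len(self.variables)

    def label_to_code(self, label: str) -> int:
        for v in self.variables:
            if v.label == label:
                return v.code
        raise KeyError(f"{label!r} is not a state of trait {self.key!r}")


@dataclass(frozen=True)
class TraitCatalog:
    """Ordered collection of trait descriptors with a global variable numbering."""

    traits: tuple[TraitDescriptor, ...]
    version: str = ""
    _by_key: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.traits:
            raise CatalogError("catalogue has no traits")
        keys = [t.key for t in self.traits]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise CatalogError(f"duplicate trait key {dup!r}")
        codes = [v.code for t in self.traits for v in t.variables]
        if len(set(codes)) != len(codes):
            dup_c = next(c for c in codes if codes.count(c) > 1)
            raise CatalogError(f"variable code {dup_c} assigned more than once")
        if sorted(codes) != list(range(1, len(codes) + 1)):
            warnings.warn(
                "variable codes are not a contiguous 1..V sequence; "
                "column positions follow code rank order",
                stacklevel=2,
            )
        object.__setattr__(self, "_by_key", {t.key: t for t in self.traits})

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_variables(self) -> int:
        """Total number of variables V across all traits."""
        return sum(t.n_states for t in self.traits)

    @property
    def trait_keys(self) -> list[str]:
        return [t.key for t in self.traits]

    def __getitem__(self, key: str) -> TraitDescriptor:
        return self._by_key[key]

    def __contains__(self, key: str) -> bool:
        return key in self._by_key

    def iter_variables(self) -> Iterator[VariableDef]:
        """All variables in global code order."""
        return iter(sorted((v for t in self.traits for v in t.variables), key=lambda v: v.code))

    def column_index(self) -> dict[int, int]:
        """Map variable code -> 0-based column position (code rank order)."""
        return {v.code: j for j, v in enumerate(self.iter_variables())}


def load_catalog(path: Union[PathLike, IO[str]], version: str = "") -> TraitCatalog:
    """Parse a catalogue file.

    The format is one record per variable:
    ``trait_key<TAB>trait_name<TAB>variable_code<TAB>variable_label``
    with a mandatory header line; ``#`` lines are comments. Trait order and
    within-trait variable order follow the file.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
        src = getattr(path, "name", "<stream>")
    else:
        p = Path(path)
        lines = p.read_text(encoding="utf-8").splitlines()
        src = str(p)

    rows: list[tuple[str, str, int, str]] = []
    header_seen = False
    for ln_no, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if not header_seen:
            header = [c.strip() for c in line.split("\t")]
            if header[:4] != ["trait_key", "trait_name", "variable_code", "variable_label"]:
                raise CatalogError(f"{src}: bad or missing header line: {line!r}")
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise CatalogError(f"{src}:{ln_no}: expected 4 tab-separated fields, got {len(parts)}")
        key, name, code_s, label = (p.strip() for p in parts)
        try:
            code = int(code_s)
        except ValueError as exc:
            raise CatalogError(f"{src}:{ln_no}: variable code {code_s!r} is not an integer") from exc
        rows.append((key, name, code, label))
    if not header_seen:
        raise CatalogError(f"{src}: file is empty or has no header")
    if not rows:
        raise CatalogError(f"{src}: no variable records")

    # group consecutively by trait key, preserving first-appearance order
    order: list[str] = []
    names: dict[str, str] = {}
    grouped: dict[str, list[VariableDef]] = {}
    for key, name, code, label in rows:
        if key not in grouped:
            order.append(key)
            names[key] = name
            grouped[key] = []
        elif names[key] != name:
            raise CatalogError(f"{src}: trait {key!r} has conflicting names {names[key]!r} / {name!r}")
        grouped[key].append(VariableDef(code=code, label=label, trait_key=key))

    traits = tuple(
        TraitDescriptor(key=k, name=names[k], variables=tuple(grouped[k])) for k in order
    )
    return TraitCatalog(traits=traits, version=version)


def save_catalog(cat: TraitCatalog, path: PathLike) -> None:
    """Write a catalogue in the same format :func:`load_catalog` reads."""
    out = ["trait_key\ttrait_name\tvariable_code\tvariable_label"]
    for t in cat.traits:
        for v in t.variables:
            out.append(f"{t.key}\t{t.name}\t{v.code}\t{v.label}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def catalog_summary(cat: TraitCatalog) -> dict:
    """Per-trait state counts plus V, mean states/trait (2 dp) and extremes."""
    counts = {t.key: t.n_states for t in cat.traits}
    v = cat.n_variables
    mean = round(v / cat.n_traits, 2)
    max_key = max(counts, key=lambda k: (counts[k],))
    min_key = min(counts, key=lambda k: (counts[k],))
    return {
        "counts": counts,
        "V": v,
        "n_traits": cat.n_traits,
        "mean_per_trait": mean,
        "max_trait": (max_key, counts[max_key]),
        "min_trait": (min_key, counts[min_key]),
    }


def odisha_asg_catalog() -> TraitCatalog:
    """The bundled 24-trait / 70-variable Odisha ASG rice descriptor catalogue."""
    ref = resources.files("phenodiv.data").joinpath("odisha_asg_catalog.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_catalog(fh, version="odisha-asg-1")
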