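"""Genotype x trait categorical matrix, validation, one-hot encoding, frequencies.

Every genotype (accession) carries one categorical state per trait, validated
against a :class:`~phenodiv.catalog.TraitCatalog`. The one-hot
:class:`BinaryMatrix` view has one column per catalogue variable, in global
code order, with exactly one 1 among each fully-scored trait's columns — the
presence/absence coding used throughout: diversity statistics, distances,
AMOVA, ordination and the phenoprint barcodes all consume it.

Missing states are permitted: a missing cell masks that genotype out of that
trait's denominator only. Accession ids are mandatory and unique; genotype
names are annotation (landrace names repeat across collections).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .catalog import TraitCatalog

__all__ = [
    "GenotypeRecord",
    "TraitMatrix",
    "BinaryMatrix",
    "FrequencyTable",
    "MatrixError",
    "load_matrix",
    "save_matrix",
    "encode_binary",
    "decode_binary",
    "frequencies",
    "pairwise_trait_diff",
]

PathLike = Union[str, Path]
MISSING = -1


class MatrixError(ValueError):
    """Raised on malformed or catalogue-inconsistent matrix data."""


@dataclass(frozen=True)
class GenotypeRecord:
    accession_id: str
    name: str = ""
    group: Optional[str] = None
    states: dict[str, Optional[str]] = field(default_factory=dict)


@dataclass
class TraitMatrix:
    """Ordered panel of genotype records tied to a catalogue."""

    catalog: TraitCatalog
    records: list[GenotypeRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise MatrixError("matrix must contain at least one genotype")
        ids = [r.accession_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise MatrixError(f"duplicate accession_id {dup!r}")
        for r in self.records:
            for key, label in r.states.items():
                if key not in self.catalog:
                    raise MatrixError(f"{r.accession_id}: unknown trait {key!r}")
                if label is not None:
                    trait = self.catalog[key]
                    if label not in {v.label for v in trait.variables}:
                        raise MatrixError(
                            f"{r.accession_id}: {label!r} is not a state of trait {key!r}"
                        )
        self._index = {r.accession_id: i for i, r in enumerate(self.records)}

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.accession_id for r in self.records]

    @property
    def groups(self) -> list[Optional[str]]:
        return [r.group for r in self.records]

    def record(self, accession_id: str) -> GenotypeRecord:
        try:
            return self.records[self._index[accession_id]]
        except KeyError:
            raise MatrixError(f"unknown accession {accession_id!r}") from None

    def state_indices(self) -> np.ndarray:
        """N x T array of within-trait state positions; missing cells are -1."""
        t_keys = self.catalog.trait_keys
        label_pos = {
            t.key: {v.label: j for j, v in enumerate(t.variables)} for t in self.catalog.traits
        }
        out = np.full((self.n, len(t_keys)), MISSING, dtype=np.int64)
        for i, rec in enumerate(self.records):
            for j, key in enumerate(t_keys):
                label = rec.states.get(key)
                if label is not None:
                    out[i, j] = label_pos[key][label]
        return out

    def subset(self, ids: Sequence[str]) -> "TraitMatrix":
        return TraitMatrix(self.catalog, [self.record(i) for i in ids])

    def group_members(self, group: str) -> list[str]:
        members = [r.accession_id for r in self.records if r.group == group]
        if not members:
            raise MatrixError(f"no genotypes in group {group!r}")
        return members

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"accession_id": r.accession_id, "name": r.name, "group": r.group or ""}
            for key in self.catalog.trait_keys:
                row[key] = r.states.get(key) or ""
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class BinaryMatrix:
    """One-hot presence/absence view: rows = genotypes, columns = variables 1..V."""

    catalog: TraitCatalog
    ids: list[str]
    groups: list[Optional[str]]
    data: np.ndarray        # N x V uint8, 0/1
    state_idx: np.ndarray   # N x T within-trait positions, -1 missing
    trait_slices: dict[str, slice]

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def v(self) -> int:
        return self.data.shape[1]

    def scored(self) -> np.ndarray:
        """N x T boolean: trait scored for genotype."""
        return self.state_idx != MISSING

    def row_for(self, accession_id: str) -> np.ndarray:
        try:
            return self.data[self.ids.index(accession_id)]
        except ValueError:
            raise MatrixError(f"unknown accession {accession_id!r}") from None


@dataclass
class FrequencyTable:
    """Per-trait sample state proportions with per-trait denominators."""

    catalog: TraitCatalog
    p: dict[str, np.ndarray]   # trait_key -> proportions in catalogue state order
    n: dict[str, int]          # trait_key -> genotypes scored

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.catalog.traits:
            for j, v in enumerate(t.variables):
                rows.append(
                    {
                        "trait_key": t.key,
                        "variable_code": v.code,
                        "variable_label": v.label,
                        "p": self.p[t.key][j],
                        "n": self.n[t.key],
                    }
                )
        return pd.DataFrame(rows)


def load_matrix(path: PathLike, catalog: TraitCatalog, sep: str = "\t") -> TraitMatrix:
    """Read a delimited genotype x trait matrix and validate it.

    Layout: columns ``accession_id``, ``name``, ``group`` then one column per
    trait key; cells hold variable labels, empty cell = missing. ``#`` lines
    are comments.
    """
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)
    required = {"accession_id", "name", "group"}
    if not required.issubset(df.columns):
        raise MatrixError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    trait_cols = [c for c in df.columns if c not in required]
    unknown = [c for c in trait_cols if c not in catalog]
    if unknown:
        raise MatrixError(f"{path}: unknown trait columns {unknown}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        states: dict[str, Optional[str]] = {}
        for key in trait_cols:
            label = d[key].strip()
            if label and label not in {v.label for v in catalog[key].variables}:
                raise MatrixError(
                    f"{path} row {row_no} ({d['accession_id']}): "
                    f"{label!r} is not a state of trait {key!r}"
                )
            states[key] = label or None
        records.append(
            GenotypeRecord(
                accession_id=d["accession_id"],
                name=d["name"],
                group=d["group"] or None,
                states=states,
            )
        )
    return TraitMatrix(catalog, records)


def save_matrix(tm: TraitMatrix, path: PathLike, sep: str = "\t", header: str = "") -> None:
    """Write a matrix in the format :func:`load_matrix` reads."""
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    cols = ["accession_id", "name", "group"] + tm.catalog.trait_keys
    lines.append(sep.join(cols))
    for r in tm.records:
        cells = [r.accession_id, r.name, r.group or ""]
        cells += [r.states.get(k) or "" for k in tm.catalog.trait_keys]
        lines.append(sep.join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def encode_binary(tm: TraitMatrix) -> BinaryMatrix:
    """One-hot encode: column j holds catalogue variable code j+1 (rank order)."""
    state_idx = tm.state_indices()
    col_of = tm.catalog.column_index()
    v_total = tm.catalog.n_variables
    data = np.zeros((tm.n, v_total), dtype=np.uint8)
    trait_slices: dict[str, slice] = {}
    for t_pos, trait in enumerate(tm.catalog.traits):
        cols = [col_of[v.code] for v in trait.variables]
        lo, hi = min(cols), max(cols)
        trait_slices[trait.key] = slice(lo, hi + 1)
        for i in range(tm.n):
            s = state_idx[i, t_pos]
            if s != MISSING:
                data[i, cols[s]] = 1
    return BinaryMatrix(
        catalog=tm.catalog,
        ids=tm.ids,
        groups=tm.groups,
        data=data,
        state_idx=state_idx,
        trait_slices=trait_slices,
    )


def decode_binary(bm: BinaryMatrix) -> TraitMatrix:
    """Invert :func:`encode_binary` exactly."""
    records = []
    for i, acc in enumerate(bm.ids):
        states: dict[str, Optional[str]] = {}
        for t_pos, trait in enumerate(bm.catalog.traits):
            s = bm.state_idx[i, t_pos]
            states[trait.key] = None if s == MISSING else trait.variables[s].label
        records.append(
            GenotypeRecord(accession_id=acc, name="", group=bm.groups[i], states=states)
        )
    return TraitMatrix(bm.catalog, records)


def frequencies(tm: TraitMatrix, subset: Optional[Sequence[str]] = None) -> FrequencyTable:
    """Per-trait state proportions, overall or for a subset of accession ids.

    Variables never observed keep p = 0 but stay listed, so every vector has
    the trait's full catalogue length.
    """
    if subset is not None:
        if len(subset) == 0:
            raise MatrixError("empty subset")
        tm = tm.subset(list(subset))
    state_idx = tm.state_indices()
    p: dict[str, np.ndarray] = {}
    n: dict[str, int] = {}
    for t_pos, trait in enumerate(tm.catalog.traits):
        col = state_idx[:, t_pos]
        scored = col != MISSING
        n_t = int(scored.sum())
        counts = np.bincount(col[scored], minlength=trait.n_states).astype(float)
        p[trait.key] = counts / n_t if n_t > 0 else counts
        n[trait.key] = n_t
    return FrequencyTable(catalog=tm.catalog, p=p, n=n)


def pairwise_trait_diff(tm: TraitMatrix, id_a: str, id_b: str) -> dict:
    """Traits at which two genotypes differ, excluding traits missing in either."""
    ra, rb = tm.record(id_a), tm.record(id_b)
    differing, skipped = [], []
    for key in tm.catalog.trait_keys:
        sa, sb = ra.states.get(key), rb.states.get(key)
        if sa is None or sb is None:
            skipped.append(key)
        elif sa != sb:
            differing.append(key)
    return {"differing": differing, "count": len(differing), "skipped": skipped}
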