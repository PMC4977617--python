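"""Diversity statistics for categorical descriptor data.

Per trait, with state proportions p_i over the catalogue's allowed states:

* Na — observed state count, ``#{p_i > 0}``
* Ne — effective state number, ``1 / sum(p_i^2)``
* h  — Nei gene diversity, ``1 - sum(p_i^2)`` (so h = 1 - 1/Ne identically)
* I  — Shannon information index, ``-sum(p_i ln p_i)`` with 0 ln 0 := 0

Panel-level summaries add percent polymorphism (%P, share of variables
segregating within a subset), the probability of identity PI (chance that two
independent genotypes match at every polymorphic trait, assuming traits
independent: the product over traits of sum(p_i^2)) and its reciprocal, the
differentiation capacity.

The plug-in (maximum-likelihood) form of h is the default; the small-sample
corrected form ``n/(n-1) * (1 - sum p^2)`` is available via ``unbiased=True``.
Rounding happens only at presentation, half-up to 3 decimals to match the
conventions of germplasm characterization tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import BinaryMatrix, FrequencyTable, MatrixError, TraitMatrix, frequencies

__all__ = [
    "TraitDiversity",
    "DiversitySummary",
    "trait_diversity",
    "diversity_table",
    "percent_polymorphic",
    "probability_of_identity",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, the convention of printed diversity tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TraitDiversity:
    trait_key: str
    na: int
    ne: float
    h: float
    i: float
    n: int


@dataclass
class DiversitySummary:
    """Per-trait diversity table with cross-trait means/sds and %P."""

    table: pd.DataFrame          # columns: trait_key, Na, Ne, He, I, n
    percent_polymorphic: float
    pi: float
    capacity: float

    @property
    def means(self) -> pd.Series:
        return self.table[["Na", "Ne", "He", "I"]].mean()

    @property
    def stds(self) -> pd.Series:
        return self.table[["Na", "Ne", "He", "I"]].std(ddof=1)


def trait_diversity(
    p: Sequence[float], n: int = 1, trait_key: str = "", unbiased: bool = False
) -> TraitDiversity:
    """Diversity statistics for one trait from its state proportions."""
    p = np.asarray(p, dtype=float)
    if n < 1:
        raise ValueError("denominator n must be >= 1")
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError(f"proportions do not form a distribution (sum={p.sum()!r})")
    sumsq = float(np.sum(p * p))
    na = int(np.count_nonzero(p))
    ne = 1.0 / sumsq
    h = 1.0 - sumsq
    if unbiased:
        if n < 2:
            raise ValueError("unbiased estimator needs n >= 2")
        h = n / (n - 1.0) * h
    nz = p[p > 0]
    i = float(-(nz * np.log(nz)).sum())
    return TraitDiversity(trait_key=trait_key, na=na, ne=ne, h=h, i=i, n=n)


def _summary_from_freqs(
    ft: FrequencyTable,
    unbiased: bool,
    pp_denominator: str,
) -> DiversitySummary:
    rows = []
    for t in ft.catalog.traits:
        td = trait_diversity(ft.p[t.key], max(ft.n[t.key], 1), t.key, unbiased=unbiased)
        rows.append(
            {"trait_key": td.trait_key, "Na": td.na, "Ne": td.ne, "He": td.h, "I": td.i,
             "n": td.n}
        )
    table = pd.DataFrame(rows)
    n_poly_vars = sum(
        int(np.count_nonzero((p > 0) & (p < 1))) for p in ft.p.values()
    )
    if pp_denominator == "catalog":
        denom = ft.catalog.n_variables
    elif pp_denominator == "observed":
        denom = sum(int(np.count_nonzero(p > 0)) for p in ft.p.values())
    else:
        raise ValueError("pp_denominator must be 'catalog' or 'observed'")
    pct_p = 100.0 * n_poly_vars / denom if denom else 0.0
    pi, cap = probability_of_identity(ft)
    return DiversitySummary(table=table, percent_polymorphic=pct_p, pi=pi, capacity=cap)


def diversity_table(
    tm: TraitMatrix,
    by_group: bool = False,
    unbiased: bool = False,
    pp_denominator: str = "catalog",
):
    """Diversity summary for a panel, overall or one summary per group.

    With ``by_group=True`` returns a dict group -> :class:`DiversitySummary`,
    frequencies computed within each group.
    """
    if not by_group:
        return _summary_from_freqs(frequencies(tm), unbiased, pp_denominator)
    out: dict[str, DiversitySummary] = {}
    seen: list[str] = []
    for g in tm.groups:
        if g is not None and g not in seen:
            seen.append(g)
    if not seen:
        raise MatrixError("no group labels present")
    for g in seen:
        ft = frequencies(tm, subset=tm.group_members(g))
        out[g] = _summary_from_freqs(ft, unbiased, pp_denominator)
    return out


def percent_polymorphic(
    bm: BinaryMatrix,
    subset: Optional[Sequence[str]] = None,
    denominator: Optional[int] = None,
) -> float:
    """100 x (variables with 0 < within-subset frequency < 1) / V.

    The denominator defaults to the catalogue's total variable count.
    """
    if subset is None:
        rows = np.arange(bm.n)
    else:
        if len(subset) == 0:
            raise MatrixError("empty subset")
        rows = np.array([bm.ids.index(s) for s in subset])
    denom = denominator if denominator is not None else bm.catalog.n_variables
    poly = 0
    for key, sl in bm.trait_slices.items():
        t_pos = bm.catalog.trait_keys.index(key)
        scored = bm.scored()[rows, t_pos]
        if not scored.any():
            continue
        colsum = bm.data[rows][scored][:, sl].sum(axis=0)
        n_t = int(scored.sum())
        poly += int(np.count_nonzero((colsum > 0) & (colsum < n_t)))
    return 100.0 * poly / denom


def probability_of_identity(ft: FrequencyTable) -> tuple[float, float]:
    """(PI, differentiation capacity 1/PI).

    PI multiplies the per-trait match probabilities sum(p_i^2) over all
    traits; monomorphic traits contribute a factor of 1, so restricting to
    polymorphic traits gives the same product.
    """
    pi = 1.0
    for p in ft.p.values():
        s = float(np.sum(p * p))
        if s > 0:
            pi *= s
    return pi, 1.0 / pi
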