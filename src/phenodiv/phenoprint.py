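"""Phenoprint barcodes, duplicate detection and core-subset selection.

A phenoprint is a genotype's ordered presence/absence vector over all
catalogue variables rendered as a barcode: one row per genotype, one column
per variable in global code order, a black bar where the state is present and
a grey bar where absent. Because the geometry and attribute ordering are
fixed, identical inputs yield byte-identical SVG — the files are diffable and
usable as golden references.

Core-subset selection is a set-cover problem over the variables observed in
the panel (unobserved catalogue states cannot be covered). Small panels are
solved exactly by iterative-deepening branch and bound; larger panels use
greedy selection — repeatedly pick the genotype adding the most uncovered
variables, ties resolving to panel order — which carries the classical
(ln V + 1) approximation guarantee. Both strategies are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .diversity import diversity_table
from .matrix import BinaryMatrix, MatrixError, decode_binary

__all__ = ["CoreSet", "render_phenoprint", "find_duplicates", "core_subset"]

PathLike = Union[str, Path]

_PRESENT = "#000000"
_ABSENT = "#bfbfbf"
_MISSING = "#ffffff"


@dataclass
class CoreSet:
    ids: list[str]                 # selection order
    covered_codes: list[int]       # variable codes covered by the selection
    coverage: float                # fraction of observed variables covered
    threshold: float
    n_observed_variables: int
    mean_nei_h: float              # mean per-trait gene diversity within the subset
    coverage_path: list[float]     # coverage after each greedy step


def render_phenoprint(
    bm: BinaryMatrix,
    ids: Optional[Sequence[str]] = None,
    path: Optional[PathLike] = None,
    bar_width: int = 6,
    bar_height: int = 14,
    gap: int = 2,
    label_space: int = 90,
) -> str:
    """Render barcode rows as SVG text; optionally write it to ``path``.

    Black = state present, grey = absent, white = trait not scored. Geometry
    is deterministic, so equal inputs produce byte-identical output.
    """
    if ids is None:
        ids = list(bm.ids)
    rows = []
    for acc in ids:
        if acc not in bm.ids:
            raise MatrixError(f"unknown accession {acc!r}")
        rows.append(bm.ids.index(acc))
    v = bm.v
    width = label_space + v * bar_width
    height = len(rows) * (bar_height + gap)
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
    ]
    scored = bm.scored()
    col_trait = []  # trait position of each column, for the missing mask
    t_keys = bm.catalog.trait_keys
    for key in t_keys:
        sl = bm.trait_slices[key]
        col_trait.extend([t_keys.index(key)] * (sl.stop - sl.start))
    for r, (acc, i) in enumerate(zip(ids, rows)):
        y = r * (bar_height + gap)
        out.append(
            f'<text x="0" y="{y + bar_height - 3}" font-family="monospace" '
            f'font-size="10">{_xml_escape(acc)}</text>'
        )
        for j in range(v):
            if not scored[i, col_trait[j]]:
                fill = _MISSING
            else:
                fill = _PRESENT if bm.data[i, j] else _ABSENT
            x = label_space + j * bar_width
            out.append(
                f'<rect x="{x}" y="{y}" width="{bar_width}" height="{bar_height}" '
                f'fill="{fill}"/>'
            )
    out.append("</svg>")
    svg = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(svg, encoding="utf-8")
    return svg


def _xml_escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def find_duplicates(bm: BinaryMatrix) -> list[list[str]]:
    """Groups of genotypes with bit-identical phenoprints (missing mask
    included). An empty result means every genotype is distinguishable."""
    seen: dict[bytes, list[str]] = {}
    scored = bm.scored()
    for i, acc in enumerate(bm.ids):
        key = bm.data[i].tobytes() + scored[i].tobytes()
        seen.setdefault(key, []).append(acc)
    return [grp for grp in seen.values() if len(grp) > 1]


def _greedy_cover(masks: list[int], target: int) -> list[int]:
    covered = 0
    chosen: list[int] = []
    remaining = list(range(len(masks)))
    while bin(covered).count("1") < target and remaining:
        gains = [bin(masks[i] & ~covered).count("1") for i in remaining]
        best = max(gains)
        if best == 0:
            break
        pick = remaining[gains.index(best)]  # first index wins ties
        chosen.append(pick)
        remaining.remove(pick)
        covered |= masks[pick]
    return chosen


def _exact_cover(masks: list[int], target: int) -> list[int]:
    """Minimum-cardinality subset whose union covers >= target variables.

    Iterative deepening with a marginal-gain bound; among minimum-size
    solutions the first one in depth-first panel order is returned, so the
    result is deterministic.
    """
    n = len(masks)
    upper = _greedy_cover(masks, target)
    max_gain = max((bin(m).count("1") for m in masks), default=0)
    if max_gain == 0:
        return []
    for size in range(1, len(upper) + 1):
        def dfs(start: int, covered: int, left: int) -> Optional[list[int]]:
            have = bin(covered).count("1")
            if have >= target:
                return []
            if left == 0 or have + left * max_gain < target:
                return None
            for i in range(start, n - left + 1):
                if bin(masks[i] & ~covered).count("1") == 0:
                    continue
                rest = dfs(i + 1, covered | masks[i], left - 1)
                if rest is not None:
                    return [i] + rest
            return None

        sol = dfs(0, 0, size)
        if sol is not None:
            return sol
    return upper


def core_subset(bm: BinaryMatrix, threshold: float = 0.98, method: str = "auto") -> CoreSet:
    """Minimal subset of genotypes covering >= ``threshold`` of the observed
    variables.

    ``method``: ``"exact"`` (branch and bound), ``"greedy"``, or ``"auto"``
    (exact for panels of up to 16 genotypes, greedy beyond). The returned ids
    are ordered by sequential marginal gain, so the coverage path is strictly
    increasing.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    if method not in ("auto", "exact", "greedy"):
        raise ValueError(f"unknown method {method!r}")
    observed = bm.data.any(axis=0)
    universe = int(observed.sum())
    masks = [
        int.from_bytes(np.packbits(bm.data[i].astype(bool) & observed).tobytes(), "big")
        for i in range(bm.n)
    ]
    target = int(np.ceil(threshold * universe - 1e-9)) if universe else 0
    use_exact = method == "exact" or (method == "auto" and bm.n <= 16)
    chosen = _exact_cover(masks, target) if use_exact else _greedy_cover(masks, target)

    # order by sequential marginal gain (greedy order within the chosen set)
    ordered: list[int] = []
    covered_mask = 0
    pool = list(chosen)
    while pool:
        gains = [bin(masks[i] & ~covered_mask).count("1") for i in pool]
        pick = pool[gains.index(max(gains))]
        ordered.append(pick)
        pool.remove(pick)
        covered_mask |= masks[pick]
    path = []
    covered = np.zeros(bm.v, dtype=bool)
    for i in ordered:
        covered |= bm.data[i].astype(bool) & observed
        path.append(covered.sum() / universe if universe else 0.0)
    chosen = ordered
    coverage = path[-1] if path else 0.0
    codes = [v.code for v, c in zip(bm.catalog.iter_variables(), covered) if c]
    if chosen:
        sub_tm = decode_binary(bm).subset([bm.ids[i] for i in chosen])
        mean_h = float(diversity_table(sub_tm).table["He"].mean())
    else:
        mean_h = float("nan")
    return CoreSet(
        ids=[bm.ids[i] for i in chosen],
        covered_codes=codes,
        coverage=coverage,
        threshold=threshold,
        n_observed_variables=universe,
        mean_nei_h=mean_h,
        coverage_path=path,
    )
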