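"""Principal component analysis of the one-hot matrix and trait-importance ranking.

PCA runs on the column-centered (not scaled) binary matrix via SVD. One-hot
columns of a trait are linearly dependent (they sum to 1 per scored trait);
all columns are kept and the resulting rank deficiency accepted, so loadings
do not depend on an arbitrary choice of reference state.

Trait importance aggregates the eigenvalue-weighted squared loadings of a
trait's columns over the retained components; summed over all traits and all
components this recovers the total variance exactly, so the scores partition
variance by trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import BinaryMatrix

__all__ = ["PcaResult", "pca", "rank_traits"]


@dataclass
class PcaResult:
    eigenvalues: np.ndarray          # non-increasing, length = min(N-1, V)
    proportion: np.ndarray           # of total variance, sums to 1 over nonzero
    cumulative: np.ndarray
    scores: np.ndarray               # N x C genotype coordinates
    loadings: np.ndarray             # V x C unit-norm variable loadings
    column_means: np.ndarray
    variable_codes: list[int]
    trait_keys: list[str]            # owning trait of each column
    imputed: bool                    # missing cells replaced by column means
    degenerate: bool                 # all-constant input

    def scree(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.eigenvalues) + 1),
                "eigenvalue": self.eigenvalues,
                "proportion": self.proportion,
                "cumulative": self.cumulative,
            }
        )


def pca(bm: BinaryMatrix) -> PcaResult:
    """Centered PCA of the one-hot matrix.

    Missing trait blocks are imputed by column means (flagged on the result).
    Sign convention: within each component the largest-magnitude loading is
    positive, which makes the decomposition reproducible across runs.
    """
    if bm.n < 2:
        raise ValueError("PCA needs at least two genotypes")
    x = bm.data.astype(float)
    imputed = False
    scored = bm.scored()
    if not scored.all():
        imputed = True
        for key, sl in bm.trait_slices.items():
            t_pos = bm.catalog.trait_keys.index(key)
            miss = ~scored[:, t_pos]
            if miss.any():
                ok = scored[:, t_pos]
                col_mean = x[ok][:, sl].mean(axis=0) if ok.any() else 0.0
                x[np.ix_(miss, range(sl.start, sl.stop))] = col_mean
    means = x.mean(axis=0)
    xc = x - means
    degenerate = bool(np.allclose(xc, 0.0))
    if degenerate:
        warnings.warn("matrix is constant; all eigenvalues are zero", stacklevel=2)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    c = min(bm.n - 1, bm.v)
    u, s, vt = u[:, :c], s[:c], vt[:c]
    eig = s**2 / (bm.n - 1)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(c):
        idx = int(np.argmax(np.abs(vt[j])))
        if vt[j, idx] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    total = eig.sum()
    prop = eig / total if total > 0 else np.zeros_like(eig)
    codes = [v.code for v in bm.catalog.iter_variables()]
    owner = [v.trait_key for v in bm.catalog.iter_variables()]
    return PcaResult(
        eigenvalues=eig,
        proportion=prop,
        cumulative=np.cumsum(prop),
        scores=u * s,
        loadings=vt.T,
        column_means=means,
        variable_codes=codes,
        trait_keys=owner,
        imputed=imputed,
        degenerate=degenerate,
    )


def rank_traits(result: PcaResult, n_components: int = 3) -> pd.DataFrame:
    """Traits ordered by eigenvalue-weighted squared loadings on the first
    ``n_components`` components; ties resolve to catalogue order."""
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    avail = len(result.eigenvalues)
    if n_components > avail:
        warnings.warn(
            f"requested {n_components} components, only {avail} available", stacklevel=2
        )
        n_components = avail
    lam = result.eigenvalues[:n_components]
    load2 = result.loadings[:, :n_components] ** 2
    per_col = load2 @ lam
    order_keys = list(dict.fromkeys(result.trait_keys))
    scores = {k: 0.0 for k in order_keys}
    for col_key, val in zip(result.trait_keys, per_col):
        scores[col_key] += float(val)
    df = pd.DataFrame(
        {
            "trait_key": order_keys,
            "importance": [scores[k] for k in order_keys],
            "catalog_position": range(len(order_keys)),
        }
    )
    df = df.sort_values(
        ["importance", "catalog_position"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="catalog_position")
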