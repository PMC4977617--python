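"""Analysis of molecular variance (AMOVA) on one-hot descriptor profiles.

One level of hierarchy: variation among groups (districts) versus within
groups. Sums of squares come from squared Euclidean distances between one-hot
rows,

    SS_total  = (1/N)  * sum_{i<j} d2_ij
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d2_ij
    SS_among  = SS_total - SS_within

with df_among = G - 1, df_within = N - G (one haploid observation per
genotype). Variance components follow the standard moment equations:
sigma2_w = MS_within and sigma2_a = (MS_among - MS_within)/n0 with
n0 = (N - sum n_g^2 / N)/(G - 1). Phi_ST = sigma2_a/(sigma2_a + sigma2_w);
negative among-group components are floored at zero for percentage reporting
while the raw value is retained. Significance is a label permutation test
with the add-one correction p = (#{Phi* >= Phi_obs} + 1)/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import BinaryMatrix

__all__ = ["AmovaResult", "amova"]


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    df_total: int
    ss_among: float
    ss_within: float
    ss_total: float
    ms_among: float
    ms_within: float
    sigma2_among: float       # raw moment estimate (may be negative)
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: Optional[float]
    n_permutations: int
    seed: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["Among groups", "Within groups", "Total"],
                "df": [self.df_among, self.df_within, self.df_total],
                "SS": [self.ss_among, self.ss_within, self.ss_total],
                "MS": [self.ms_among, self.ms_within, np.nan],
                "est_var": [max(self.sigma2_among, 0.0), self.sigma2_within, np.nan],
                "pct": [self.pct_among, self.pct_within, 100.0],
            }
        )


def _phi_from_groups(
    pair_d2: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[float, float, float]:
    """(SS_within, sigma2_a, phi) for a given integer group labelling."""
    n = codes.shape[0]
    ss_within = 0.0
    sizes = np.bincount(codes, minlength=n_groups)
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = pair_d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_total = pair_d2[np.triu_indices(n, 1)].sum() / n
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    n0 = (n - (sizes**2).sum() / n) / df_among
    sigma2_a = (ms_among - ms_within) / n0
    sigma2_w = ms_within
    denom = sigma2_a + sigma2_w
    phi = sigma2_a / denom if denom > 0 else 0.0
    return ss_within, sigma2_a, phi


def amova(
    bm: BinaryMatrix,
    groups: Optional[Sequence[Optional[str]]] = None,
    n_permutations: int = 10000,
    seed: Optional[int] = None,
) -> AmovaResult:
    """One-level AMOVA of a one-hot panel partitioned into groups.

    ``groups`` defaults to the matrix's own group labels; every genotype must
    carry one. Set ``n_permutations=0`` to skip the significance test.
    """
    if groups is None:
        groups = bm.groups
    groups = list(groups)
    if len(groups) != bm.n:
        raise ValueError("group labels must match the number of genotypes")
    if any(g is None for g in groups):
        raise ValueError("every genotype needs a group label for AMOVA")
    uniq = sorted(set(groups))
    g_count = len(uniq)
    if g_count < 2:
        raise ValueError("AMOVA needs at least two groups")
    if n_permutations < 0:
        raise ValueError("n_permutations must be >= 0")
    codes = np.array([uniq.index(g) for g in groups])
    x = bm.data.astype(float)
    sq = (x * x).sum(axis=1)
    pair_d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(pair_d2, 0.0)
    pair_d2 = np.maximum(pair_d2, 0.0)

    n = bm.n
    ss_total = pair_d2[np.triu_indices(n, 1)].sum() / n
    ss_within, sigma2_a, phi = _phi_from_groups(pair_d2, codes, g_count)
    ss_among = ss_total - ss_within
    df_among, df_within = g_count - 1, n - g_count
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    sigma2_w = ms_within
    a_pos = max(sigma2_a, 0.0)
    total_var = a_pos + sigma2_w
    pct_among = 100.0 * a_pos / total_var if total_var > 0 else 0.0

    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        perm_codes = codes.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm_codes)
            _, _, phi_perm = _phi_from_groups(pair_d2, perm_codes, g_count)
            if phi_perm >= phi - 1e-12:
                hits += 1
        p_value = (hits + 1) / (n_permutations + 1)

    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        df_total=n - 1,
        ss_among=ss_among,
        ss_within=ss_within,
        ss_total=ss_total,
        ms_among=ms_among,
        ms_within=ms_within,
        sigma2_among=sigma2_a,
        sigma2_within=sigma2_w,
        pct_among=pct_among,
        pct_within=100.0 - pct_among,
        phi_st=phi,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
    )
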