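"""Bayesian admixture-model clustering of categorical descriptor profiles.

The model: K latent clusters, each owning a categorical state-frequency
vector per trait (P). Every genotype i has an ancestry vector q_i on the
K-simplex; its observed state at trait t arises by first picking a cluster of
origin z_it ~ Categorical(q_i) and then a state ~ Categorical(p_{z_it, t}).
This is the classic admixture model for unlinked markers with one haploid
observation per locus; priors are Dirichlet(alpha) on each q_i (alpha fixed,
not sampled — a deliberate simplification) and Dirichlet(1) on each cluster's
per-trait frequencies.

Inference is a collapsed-free Gibbs sampler alternating z | q, P — then
q | z and P | z, all updates vectorized over genotypes and traits. The
log "probability of data" reported per run is the deviance-style estimator
mean(L) - var(L)/2 over post-burn-in sweeps, where L is the observed-data
mixture log-likelihood; the number of clusters is then chosen by the
second-order rate of change of that quantity across K divided by its
between-run standard deviation (the Delta-K heuristic), and genotypes with a
maximum membership <= 0.80 are reported as admixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .amova import amova
from .matrix import TraitMatrix, encode_binary

__all__ = [
    "StructureRun",
    "Assignment",
    "fit_structure",
    "evanno",
    "assign",
    "cluster_fst",
    "align_clusters",
]


@dataclass
class StructureRun:
    """Posterior summaries of one MCMC run at a fixed K."""

    k: int
    ids: list[str]
    trait_keys: list[str]
    q: np.ndarray                      # N x K posterior mean ancestry
    p: dict[str, np.ndarray]           # trait_key -> K x n_states posterior mean
    ln_p_data: float
    alpha: float
    burn_in: int
    reps: int
    seed: Optional[int]
    trace: np.ndarray                  # per-sweep mixture log-likelihood (all sweeps)


@dataclass
class Assignment:
    """Hard cluster assignment under the membership-threshold rule."""

    table: pd.DataFrame        # accession_id, cluster, max_membership, status
    threshold: float
    shares: np.ndarray         # mean membership per cluster

    @property
    def admixed_ids(self) -> list[str]:
        return self.table.loc[self.table["status"] == "admixed", "accession_id"].tolist()


def fit_structure(
    tm: TraitMatrix,
    k: int,
    alpha: float = 1.0,
    burn_in: int = 2000,
    reps: int = 5000,
    seed: Optional[int] = None,
) -> StructureRun:
    """Gibbs-sample the admixture model and return posterior-mean Q and P."""
    if k < 1:
        raise ValueError("K must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if burn_in < 1 or reps < 1:
        raise ValueError("burn_in and reps must be positive")
    rng = np.random.default_rng(seed)

    x = tm.state_indices()                  # N x T, -1 missing
    scored = x != -1
    n, t = x.shape
    n_states = np.array([tr.n_states for tr in tm.catalog.traits])
    s_max = int(n_states.max())
    valid = np.arange(s_max)[None, :] < n_states[:, None]     # T x S
    xc = np.where(scored, x, 0)
    t_grid = np.broadcast_to(np.arange(t), (n, t))

    # initial values: uniform ancestry, frequencies from a flat Dirichlet
    q = np.full((n, k), 1.0 / k)
    p = rng.standard_gamma(np.where(valid, 1.0, 0.0)[None, :, :] * np.ones((k, 1, 1)))
    p /= p.sum(axis=2, keepdims=True)

    q_sum = np.zeros_like(q)
    p_sum = np.zeros_like(p)
    trace = np.empty(burn_in + reps)
    kept = 0

    for sweep in range(burn_in + reps):
        # z | q, P
        pz = p[:, np.arange(t)[None, :], xc]          # K x N x T
        prob = q.T[:, :, None] * pz
        tot = prob.sum(axis=0)
        trace[sweep] = float(np.log(tot[scored]).sum())
        c = np.cumsum(prob, axis=0)
        u = rng.random((n, t)) * tot
        z = np.minimum((u[None, :, :] >= c).sum(axis=0), k - 1)

        # q | z
        one_hot = (z[:, :, None] == np.arange(k)) & scored[:, :, None]
        nz = one_hot.sum(axis=1)                      # N x K
        g = rng.standard_gamma(alpha + nz)
        q = g / g.sum(axis=1, keepdims=True)

        # P | z
        cnt = np.zeros((k, t, s_max))
        np.add.at(cnt, (z[scored], t_grid[scored], xc[scored]), 1.0)
        shape = np.where(valid[None, :, :], 1.0 + cnt, 0.0)
        g = rng.standard_gamma(shape)
        p = g / np.maximum(g.sum(axis=2, keepdims=True), 1e-300)

        if sweep >= burn_in:
            q_sum += q
            p_sum += p
            kept += 1

    q_mean = q_sum / kept
    p_mean = p_sum / kept
    post = trace[burn_in:]
    ln_p = float(post.mean() - 0.5 * post.var())
    p_by_trait = {
        tr.key: p_mean[:, j, : tr.n_states].copy()
        for j, tr in enumerate(tm.catalog.traits)
    }
    # renormalize per trait (padding columns carry no mass but be safe)
    for key in p_by_trait:
        p_by_trait[key] /= p_by_trait[key].sum(axis=1, keepdims=True)
    return StructureRun(
        k=k, ids=tm.ids, trait_keys=tm.catalog.trait_keys, q=q_mean, p=p_by_trait,
        ln_p_data=ln_p, alpha=alpha, burn_in=burn_in, reps=reps, seed=seed, trace=trace,
    )


def evanno(runs: Sequence[StructureRun]) -> pd.DataFrame:
    """Delta-K table from multiple runs per K.

    Needs at least three consecutive K values with >= 2 runs each. Delta-K is
    defined for interior K with a nonzero between-run sd; elsewhere it is NaN.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.k, []).append(r.ln_p_data)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(by_k[k]) < 2 for k in ks):
        raise ValueError("need >= 2 runs per K")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lprime = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        if k - 1 in mean and k + 1 in mean:
            lsecond = abs(mean[k + 1] - 2.0 * mean[k] + mean[k - 1])
            delta = lsecond / sd[k] if sd[k] > 0 else np.nan
        else:
            lsecond, delta = np.nan, np.nan
        rows.append(
            {"K": k, "n_runs": len(by_k[k]), "mean_lnP": mean[k], "sd_lnP": sd[k],
             "Lprime": lprime, "Lsecond": lsecond, "deltaK": delta}
        )
    return pd.DataFrame(rows)


def best_k(delta_table: pd.DataFrame) -> int:
    """K with the largest defined Delta-K."""
    valid = delta_table.dropna(subset=["deltaK"])
    if valid.empty:
        raise ValueError("no interior K has a defined Delta-K")
    return int(valid.loc[valid["deltaK"].idxmax(), "K"])


def assign(run: StructureRun, threshold: float = 0.80) -> Assignment:
    """Threshold rule: max membership above ``threshold`` assigns the genotype
    to that cluster; at or below it the genotype is reported admixed."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    arg = run.q.argmax(axis=1)
    mx = run.q.max(axis=1)
    status = np.where(mx > threshold, "assigned", "admixed")
    table = pd.DataFrame(
        {
            "accession_id": run.ids,
            "cluster": arg + 1,
            "max_membership": mx,
            "status": status,
        }
    )
    return Assignment(table=table, threshold=threshold, shares=run.q.mean(axis=0))


def cluster_fst(tm: TraitMatrix, assignment: Assignment) -> dict[int, Optional[float]]:
    """Per-cluster fixation index.

    Computed as the Phi-ST of each hard-assigned cluster against the pooled
    remainder of the panel (variance-component ratio on one-hot profiles) — a
    two-group proxy for the model-based per-cluster F. Clusters with fewer
    than 2 assigned members are reported as None.
    """
    tab = assignment.table
    clusters = sorted(tab["cluster"].unique())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    bm = encode_binary(tm)
    out: dict[int, Optional[float]] = {}
    for c in clusters:
        members = set(tab.loc[(tab["cluster"] == c) & (tab["status"] == "assigned"),
                              "accession_id"])
        if len(members) < 2 or len(members) > bm.n - 2:
            out[int(c)] = None
            continue
        labels = ["in" if i in members else "out" for i in bm.ids]
        res = amova(bm, groups=labels, n_permutations=0)
        out[int(c)] = res.phi_st
    return out


def align_clusters(q: np.ndarray, q_ref: np.ndarray) -> np.ndarray:
    """Permutation of ``q``'s columns best matching ``q_ref`` (Hungarian on
    column overlap); returns the column order to apply to ``q``."""
    if q.shape != q_ref.shape:
        raise ValueError("membership matrices must have the same shape")
    overlap = q.T @ q_ref
    row, col = linear_sum_assignment(-overlap)
    order = np.empty(q.shape[1], dtype=int)
    order[col] = row
    return order
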