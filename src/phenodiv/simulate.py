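"""Synthetic landrace panels with controlled categorical frequency structure.

The generator emulates a germplasm collection scored on qualitative
descriptors: each genotype draws one state per trait from a per-trait
frequency vector, independently across traits. Two layers of structure are
supported — geographic group labels (district of collection, sizes only, no
frequency shift) and a K-subpopulation admixture layer in which every
genotype owns a Dirichlet ancestry vector and every subpopulation its own
per-trait state frequencies.

The bundled ``odisha_like`` specification reproduces the published marginal
state frequencies of the 126-genotype Odisha aromatic short-grain rice panel
(e.g. lemma-palea colour: straw 50 %, purple furrow 14 %, brown 11 %, purple
10 %, brown furrow 10 %, black 2 %, red 2 %, brown spot 1 %) and its
19-district sample sizes. Where only a trait's modal frequency was published,
the residual mass is spread uniformly over the trait's remaining states — a
stated convention, not observed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .catalog import TraitCatalog, odisha_asg_catalog
from .matrix import GenotypeRecord, TraitMatrix

__all__ = [
    "PanelSpec",
    "AdmixtureSpec",
    "simulate_panel",
    "simulate_admixed",
    "odisha_like_spec",
    "ODISHA_DISTRICT_SIZES",
]

# District of collection -> number of genotypes in the study panel (N = 126).
ODISHA_DISTRICT_SIZES: dict[str, int] = {
    "Anugul": 2, "Balasore": 4, "Bolangir": 10, "Cuttack": 15, "Deogarh": 4,
    "Dhenkanal": 4, "Ganjam": 12, "Jajpur": 2, "Kalahandi": 10,
    "Kendrapara": 2, "Keonjhar": 5, "Koraput": 17, "Malkangiri": 8,
    "Mayurbhanj": 3, "Nayagarh": 3, "Phulbani": 2, "Puri": 13,
    "Sambalpur": 4, "Sundargarh": 6,
}

# Published marginal state frequencies (proportions). Traits absent here get a
# uniform distribution; states absent within a listed trait share the residual
# mass uniformly.
_ODISHA_MODES: dict[str, dict[str, float]] = {
    "BLS": {"Green": 0.51},
    "FLA": {"Erect": 0.44},
    "CA": {"Semi erect": 0.99},
    "ST": {"Medium": 0.55},
    "PA": {"Absent": 0.91},
    "PCA": {"Yellowish white": 0.64},
    "PMA": {"Dropping": 0.91},
    "SCL": {"Purple": 0.45},
    "PE": {"Well exserted": 0.76},
    "LSL": {"Split": 0.95},
    "LAR": {"Present": 0.99},
    "CSTG": {"White": 0.74},
    "PAB": {"Semierect": 0.86},
    "INC": {"Light gold": 0.71},
    "PSB": {"Weak": 0.63},
    "LAG": {"Erect": 0.44},
    "LPC": {
        "Straw": 0.50, "Purple Furrow": 0.14, "Brown": 0.11, "Purple": 0.10,
        "Brown Furrow": 0.10, "Black": 0.02, "Red": 0.02, "Brown Spot": 0.01,
    },
    "GT": {"Short bold": 0.47, "Medium bold": 0.51},
}


@dataclass
class PanelSpec:
    """Recipe for a synthetic panel: sizes, per-trait frequencies, seed."""

    catalog: TraitCatalog
    n: int = 126
    frequencies: dict[str, np.ndarray] = field(default_factory=dict)
    group_sizes: Optional[dict[str, int]] = None
    seed: int = 0
    exact_counts: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for t in self.catalog.traits:
            if t.key not in self.frequencies:
                self.frequencies[t.key] = np.full(t.n_states, 1.0 / t.n_states)
            p = np.asarray(self.frequencies[t.key], dtype=float)
            if p.shape != (t.n_states,):
                raise ValueError(
                    f"frequency vector for {t.key!r} has length {p.size}, "
                    f"catalogue defines {t.n_states} states"
                )
            if not np.isclose(p.sum(), 1.0, atol=1e-9) or (p < 0).any():
                raise ValueError(f"frequencies for {t.key!r} are not a distribution")
            self.frequencies[t.key] = p
        if self.group_sizes is not None and sum(self.group_sizes.values()) != self.n:
            raise ValueError("group sizes must sum to n")


@dataclass
class AdmixtureSpec:
    """K-subpopulation admixture layer on top of a panel spec.

    ``alpha`` is the symmetric Dirichlet concentration of individual ancestry
    (small alpha -> near-pure genotypes). ``divergence`` scales how far each
    subpopulation's per-trait frequencies drift from the base distribution:
    frequencies are drawn from Dirichlet(base / divergence), so larger values
    give more divergent, more nearly fixed subpopulations.
    """

    k: int
    alpha: float = 0.05
    divergence: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0 or self.divergence <= 0:
            raise ValueError("alpha and divergence must be positive")


def odisha_like_spec(
    n: int = 126,
    seed: int = 0,
    exact_counts: bool = True,
    with_groups: bool = True,
    catalog: Optional[TraitCatalog] = None,
) -> PanelSpec:
    """Panel spec matching the published Odisha ASG marginal frequencies."""
    cat = catalog if catalog is not None else odisha_asg_catalog()
    freqs: dict[str, np.ndarray] = {}
    for t in cat.traits:
        modes = _ODISHA_MODES.get(t.key)
        if modes is None:
            # monomorphic traits have one catalogue state; others get uniform
            freqs[t.key] = np.full(t.n_states, 1.0 / t.n_states)
            continue
        p = np.zeros(t.n_states)
        named = set()
        for label, prob in modes.items():
            p[[v.label for v in t.variables].index(label)] = prob
            named.add(label)
        rest = [j for j, v in enumerate(t.variables) if v.label not in named]
        residual = 1.0 - p.sum()
        if rest:
            p[rest] = residual / len(rest)
        elif abs(residual) > 1e-9:
            raise ValueError(f"frequencies for {t.key!r} do not sum to 1")
        freqs[t.key] = p
    group_sizes = None
    if with_groups:
        if n == 126:
            group_sizes = dict(ODISHA_DISTRICT_SIZES)
        else:
            # rescale district sizes to n by largest remainder
            keys = list(ODISHA_DISTRICT_SIZES)
            target = np.array([ODISHA_DISTRICT_SIZES[k] for k in keys], dtype=float)
            counts = _largest_remainder(target / target.sum(), n)
            group_sizes = {k: int(c) for k, c in zip(keys, counts) if c > 0}
    return PanelSpec(
        catalog=cat, n=n, frequencies=freqs, group_sizes=group_sizes,
        seed=seed, exact_counts=exact_counts,
    )


def _largest_remainder(p: np.ndarray, n: int) -> np.ndarray:
    """Round p*n to integer counts summing to n; ties go to earlier states."""
    raw = p * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    # stable sort: largest fractional remainder first, earlier index on ties
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _group_labels(spec: PanelSpec) -> list[Optional[str]]:
    if spec.group_sizes is None:
        return [None] * spec.n
    labels: list[Optional[str]] = []
    for g, size in spec.group_sizes.items():
        labels.extend([g] * size)
    return labels


def _build_matrix(spec: PanelSpec, state_idx: np.ndarray) -> TraitMatrix:
    labels = _group_labels(spec)
    width = len(str(spec.n))
    records = []
    for i in range(spec.n):
        states = {
            t.key: t.variables[state_idx[i, j]].label
            for j, t in enumerate(spec.catalog.traits)
        }
        records.append(
            GenotypeRecord(
                accession_id=f"SIM{i + 1:0{width}d}",
                name=f"sim-{i + 1}",
                group=labels[i],
                states=states,
            )
        )
    return TraitMatrix(spec.catalog, records)


def simulate_panel(spec: PanelSpec) -> TraitMatrix:
    """Draw a panel with independent per-trait categorical states.

    With ``exact_counts`` the realized per-trait counts equal the largest-
    remainder rounding of p*N (so frequency-based statistics are exactly
    reproducible); the assignment of states to genotypes is still shuffled
    with the seeded generator. Otherwise states are i.i.d. draws.
    """
    rng = np.random.default_rng(spec.seed)
    state_idx = np.empty((spec.n, spec.catalog.n_traits), dtype=np.int64)
    for j, t in enumerate(spec.catalog.traits):
        p = spec.frequencies[t.key]
        if spec.exact_counts:
            counts = _largest_remainder(p, spec.n)
            col = np.repeat(np.arange(t.n_states), counts)
            state_idx[:, j] = rng.permutation(col)
        else:
            state_idx[:, j] = rng.choice(t.n_states, size=spec.n, p=p)
    return _build_matrix(spec, state_idx)


def simulate_admixed(
    spec: PanelSpec, adm: AdmixtureSpec
) -> tuple[TraitMatrix, np.ndarray, dict[str, np.ndarray]]:
    """Draw an admixed panel; returns (matrix, true_Q, true_P).

    Subpopulation frequencies are drawn per trait from Dirichlet(base /
    divergence); each genotype's state for trait t comes from the mixture
    sum_k q_k P_k,t. ``true_Q`` is N x K; ``true_P`` maps trait_key to a
    K x n_states frequency matrix. K = 1 returns the base panel exactly.
    """
    if adm.k == 1:
        tm = simulate_panel(spec)
        true_q = np.ones((spec.n, 1))
        true_p = {k: v[None, :].copy() for k, v in spec.frequencies.items()}
        return tm, true_q, true_p
    if adm.k > spec.catalog.n_variables:
        import warnings

        warnings.warn("K exceeds the total number of variables", stacklevel=2)
    rng = np.random.default_rng(adm.seed)
    true_p: dict[str, np.ndarray] = {}
    for t in spec.catalog.traits:
        base = spec.frequencies[t.key]
        if t.n_states == 1:
            true_p[t.key] = np.ones((adm.k, 1))
            continue
        conc = np.maximum(base / adm.divergence, 1e-8)
        true_p[t.key] = rng.dirichlet(conc, size=adm.k)
    true_q = rng.dirichlet(np.full(adm.k, adm.alpha), size=spec.n)
    state_idx = np.empty((spec.n, spec.catalog.n_traits), dtype=np.int64)
    for j, t in enumerate(spec.catalog.traits):
        mix = true_q @ true_p[t.key]  # N x n_states
        u = rng.random(spec.n)
        state_idx[:, j] = (u[:, None] >= np.cumsum(mix, axis=1)).sum(axis=1)
    return _build_matrix(spec, state_idx), true_q, true_p
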