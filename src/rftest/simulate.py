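"""Synthetic microbiome communities and the simulation scenarios.

The generator stands in for resampling a real rarefied 16S dataset: it
produces a random rooted binary tree, clade-correlated heavy-tailed
taxon proportions (Brownian motion on the tree plus log-normal noise),
and Dirichlet-multinomial counts at a fixed per-sample depth. Named
lineages — monophyletic clades with controlled fractions of the taxon
count and of the total abundance — are registered so that
phylogenetically clustered signals can be planted:

* lineage "A": ~15% of taxa, calibrated to ~21% of total abundance;
* lineage "B" ⊂ A: ~5% of taxa, ~11% of abundance;
* lineage "C", disjoint from A: ~13% of taxa, ~12% of abundance;
* further disjoint clades "D", "E", ... for lineage sweeps.

Outcomes follow the simulation scenarios: a linear signal in the summed
(optionally per-taxon mean-normalized) abundance of a signal set, a
log2(x+1) link, a product interaction between two disjoint sets, and
row-shuffled outlier samples; S0 (beta = 0) variants provide the null
for type-I error studies, with independent or microbiome-correlated
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from statsmodels.stats.proportion import proportion_confint

from .association import rftest
from .forest import ForestConfig
from .tree import PhyloTree

__all__ = [
    "Lineage",
    "SyntheticCommunity",
    "ScenarioSpec",
    "SimulatedDataset",
    "SimulationResult",
    "scale",
    "signal_sum",
    "synth_community",
    "select_signal_set",
    "outcome_linear",
    "outcome_nonlinear",
    "outcome_interaction",
    "inject_outliers",
    "simulate_dataset",
    "estimate_error_rate",
]


# ----------------------------------------------------------------------
# community generation


@dataclass(frozen=True)
class Lineage:
    """A registered monophyletic clade usable as a signal set."""

    name: str
    node: str
    taxa: tuple[str, ...]
    otu_fraction: float
    abundance_fraction: float
    target_otu_fraction: float | None = None
    target_abundance_fraction: float | None = None


@dataclass
class SyntheticCommunity:
    """A count table, its tree, and the registry of named lineages."""

    table: pd.DataFrame  # n samples x p taxa, integer counts
    tree: PhyloTree
    lineages: dict[str, Lineage]
    depth: int
    base_proportions: pd.Series = field(repr=False, default=None)

    @property
    def n_samples(self) -> int:
        return self.table.shape[0]

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.table.columns)


def _random_binary_tree(labels: Sequence[str], rng: np.random.Generator) -> PhyloTree:
    """Random binary topology: recursive uniform splits of a shuffled list."""
    order = [labels[i] for i in rng.permutation(len(labels))]
    counter = [0]
    children: dict[str, tuple[str, str]] = {}

    def split(items: list[str]) -> str:
        if len(items) == 1:
            return items[0]
        name = f"node{counter[0]}"
        counter[0] += 1
        k = int(rng.integers(1, len(items)))
        children[name] = (split(items[:k]), split(items[k:]))
        return name

    if len(order) == 1:
        root = "node0"
        children[root] = (order[0],)
        return PhyloTree(children, root)
    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(order) + 100))
    try:
        root = split(order)
    finally:
        sys.setrecursionlimit(old)
    # re-label internal nodes in preorder for reproducible column order
    tmp = PhyloTree(children, root)
    rename = {n: f"node{i}" for i, n in enumerate(tmp.internal_nodes)}
    renamed = {
        rename[n]: tuple(rename.get(c, c) for c in kids)
        for n, kids in tmp.children.items()
    }
    return PhyloTree(renamed, rename[root])


def _brownian_leaf_values(
    tree: PhyloTree, rng: np.random.Generator, edge_sd: float, size: int = 1
) -> np.ndarray:
    """Brownian motion down the tree: a (size, n_leaves) matrix of leaf
    values, one independent realization per row."""
    value = {tree.root: np.zeros(size)}
    for node in tree.nodes:
        if node == tree.root:
            continue
        value[node] = value[tree.parent[node]] + rng.normal(0.0, edge_sd, size)
    return np.column_stack([value[leaf] for leaf in tree.leaves])


def _clade_map(tree: PhyloTree) -> dict[str, tuple[str, ...]]:
    return {n: tree.descendant_leaves(n) for n in tree.internal_nodes}


def _pick_clade(
    clades: dict[str, tuple[str, ...]],
    p: int,
    target: float,
    lo: float,
    hi: float,
    forbidden_taxa: set[str] = frozenset(),
    within: set[str] | None = None,
) -> str | None:
    best, best_dev = None, np.inf
    for node, leaves in clades.items():
        frac = len(leaves) / p
        if not lo <= frac <= hi:
            continue
        if forbidden_taxa and not forbidden_taxa.isdisjoint(leaves):
            continue
        if within is not None and (not set(leaves) < within):
            continue
        dev = abs(frac - target)
        if dev < best_dev:
            best, best_dev = node, dev
    return best


def synth_community(
    n: int = 50,
    p: int = 200,
    depth: int = 20000,
    seed=None,
    brownian_sd: float = 1.0,
    lognormal_sd: float = 1.5,
    clade_fluctuation_sd: float = 0.3,
    taxon_noise_sd: float = 1.5,
) -> SyntheticCommunity:
    """Generate a rarefied synthetic community with a lineage registry.

    Base (log) abundances combine a Brownian value accumulated down the
    tree (``brownian_sd`` per edge) with independent log-normal
    heterogeneity (``lognormal_sd``), giving a heavy-tailed mean
    composition in which related taxa have similar abundance. On top of
    the base, every sample receives its own tree-correlated Brownian
    perturbation (``clade_fluctuation_sd`` per edge) plus per-taxon
    log-normal noise (``taxon_noise_sd``): whole clades fluctuate up or
    down together from sample to sample, the across-sample covariance
    structure that makes phylogenetically clustered signals detectable
    and that real communities exhibit. Counts are multinomial at the
    fixed ``depth``, so every sample's counts sum to the depth exactly.
    The "A"/"B"/"C" lineages are calibrated to the taxon-count and
    abundance fractions given in the module docstring.
    """
    if n < 1 or p < 10 or depth < 1:
        raise ValueError("need n >= 1, p >= 10 and a positive depth")
    rng = np.random.default_rng(seed)
    taxa = [f"OTU{j + 1:04d}" for j in range(p)]
    tree = _random_binary_tree(taxa, rng)

    lam = _brownian_leaf_values(tree, rng, brownian_sd)[0] + rng.normal(
        0, lognormal_sd, p
    )
    base = pd.Series(np.exp(lam), index=list(tree.leaves))
    base /= base.sum()

    clades = _clade_map(tree)
    node_a = _pick_clade(clades, p, 0.15, 0.08, 0.25) or _pick_clade(
        clades, p, 0.15, 0.04, 0.40
    )
    if node_a is None:
        raise RuntimeError("no clade near 15% of taxa; re-seed the generator")
    taxa_a = clades[node_a]
    node_b = _pick_clade(
        clades, p, 0.05, 0.02, 0.10, within=set(taxa_a)
    ) or _pick_clade(clades, p, 0.05, 0.005, 0.12, within=set(taxa_a))
    node_c = _pick_clade(
        clades, p, 0.13, 0.06, 0.25, forbidden_taxa=set(taxa_a)
    ) or _pick_clade(clades, p, 0.13, 0.03, 0.40, forbidden_taxa=set(taxa_a))

    # per-sample composition: base x clade fluctuation x taxon noise
    pos = {t: j for j, t in enumerate(tree.leaves)}
    weights = base.to_numpy()[None, :] * np.exp(
        _brownian_leaf_values(tree, rng, clade_fluctuation_sd, size=n)
        + rng.normal(0.0, taxon_noise_sd, size=(n, p))
    )

    # calibrate the focal lineages' realized abundance shares by a
    # multiplicative fixed point on the expected composition
    groups: list[tuple[np.ndarray, float]] = []
    idx_a = np.array([pos[t] for t in taxa_a])
    if node_b is not None:
        idx_b = np.array([pos[t] for t in clades[node_b]])
        mask_ab = np.setdiff1d(idx_a, idx_b)
        groups += [(idx_b, 0.11), (mask_ab, 0.10)]
    else:  # pragma: no cover - tiny trees
        groups += [(idx_a, 0.21)]
    if node_c is not None:
        groups += [(np.array([pos[t] for t in clades[node_c]]), 0.12)]
    for _ in range(8):
        shares = weights / weights.sum(axis=1, keepdims=True)
        for idx, target in groups:
            cur = shares[:, idx].sum(axis=1).mean()
            weights[:, idx] *= target / cur

    probs = weights / weights.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, probs[i]) for i in range(n)])
    base = pd.Series(probs.mean(axis=0), index=list(tree.leaves))
    table = pd.DataFrame(
        counts, index=[f"S{i + 1:03d}" for i in range(n)], columns=list(tree.leaves)
    )

    total = counts.sum()
    col_mass = table.sum(axis=0)

    def realized(leaves: tuple[str, ...]) -> float:
        return float(col_mass.loc[list(leaves)].sum() / total)

    lineages: dict[str, Lineage] = {}

    def register(name, node, t_otu, t_ab):
        leaves = clades[node]
        lineages[name] = Lineage(
            name=name,
            node=node,
            taxa=leaves,
            otu_fraction=len(leaves) / p,
            abundance_fraction=realized(leaves),
            target_otu_fraction=t_otu,
            target_abundance_fraction=t_ab,
        )

    register("A", node_a, 0.15, 0.21)
    if node_b is not None:
        register("B", node_b, 0.05, 0.11)
    if node_c is not None:
        register("C", node_c, 0.13, 0.12)

    # further disjoint clades for lineage sweeps, top-down in preorder
    taken = set(taxa_a) | (set(clades[node_c]) if node_c is not None else set())
    extra = 0
    for node in tree.internal_nodes:
        leaves = clades[node]
        frac = len(leaves) / p
        if not 0.03 <= frac <= 0.25:
            continue
        if not taken.isdisjoint(leaves):
            continue
        name = chr(ord("D") + extra)
        if name > "Z":  # pragma: no cover
            break
        register(name, node, None, None)
        taken |= set(leaves)
        extra += 1

    return SyntheticCommunity(
        table=table,
        tree=tree,
        lineages=lineages,
        depth=depth,
        base_proportions=base,
    )


# ----------------------------------------------------------------------
# signal sets and outcomes


def select_signal_set(
    community: SyntheticCommunity,
    signal_type: str,
    density: float,
    seed=None,
) -> tuple[str, ...]:
    """Choose the set of signal taxa.

    Clustered signals use the registered lineage whose taxon fraction is
    closest to the requested density (so 5% picks "B", nested inside the
    15% lineage "A"). Random signals are drawn uniformly without
    replacement as a prefix of a seed-determined permutation of the
    taxa, which makes lower-density sets nested inside higher-density
    ones for the same seed.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    taxa = community.taxa
    p = len(taxa)
    if signal_type == "random":
        k = max(1, round(density * p))
        perm = np.random.default_rng(seed).permutation(p)
        return tuple(taxa[i] for i in perm[:k])
    if signal_type != "clustered":
        raise ValueError(f"unknown signal_type {signal_type!r}")
    # the focal nested pair B < A takes precedence near its design
    # densities so that 5% and 15% clustered sets are nested
    for name in ("B", "A"):
        lin = community.lineages.get(name)
        if lin is not None and abs(lin.otu_fraction - density) / density <= 0.25:
            return lin.taxa
    best, best_rel = None, np.inf
    for lin in community.lineages.values():
        rel = abs(lin.otu_fraction - density) / density
        if rel < best_rel:
            best, best_rel = lin, rel
    if best is None or best_rel > 0.5:
        raise ValueError(
            f"no registered lineage within 50% of density {density}; "
            f"available fractions: "
            f"{sorted(round(l.otu_fraction, 3) for l in community.lineages.values())}"
        )
    return best.taxa


def scale(v: np.ndarray) -> np.ndarray:
    """Standardize to sample mean 0 and (n-1 denominator) sd 1."""
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot scale a constant vector (degenerate signal)")
    return (v - v.mean()) / sd


def signal_sum(
    table: pd.DataFrame,
    taxa: Sequence[str],
    link: str = "identity",
    mean_normalize: bool = False,
    on_absent: str = "error",
) -> np.ndarray:
    """Per-sample summed signal abundance, optionally linked/normalized.

    ``link="log2p1"`` replaces x by log2(x + 1) before summing;
    ``mean_normalize`` divides each taxon by its across-sample mean
    abundance first (so no single abundant taxon dominates the sum).
    A taxon absent from every sample makes the normalization a 0/0;
    ``on_absent="error"`` (default) rejects such input, while
    ``on_absent="drop"`` excludes those taxa from the sum (they
    contribute zero regardless) — the scenario engines use the latter,
    erroring only when the entire signal set is absent.
    """
    X = table.loc[:, list(taxa)].to_numpy(dtype=float)
    if link == "log2p1":
        X = np.log2(X + 1.0)
    elif link != "identity":
        raise ValueError(f"unknown link {link!r}")
    if mean_normalize:
        mbar = X.mean(axis=0)
        dead = mbar == 0
        if dead.all():
            raise ValueError("every signal taxon is absent from every sample")
        if dead.any():
            if on_absent == "error":
                names = [t for t, d in zip(taxa, dead) if d]
                raise ValueError(
                    "mean normalization undefined: taxa absent in every "
                    f"sample: {names[:5]}"
                )
            if on_absent != "drop":
                raise ValueError(f"unknown on_absent {on_absent!r}")
            X = X[:, ~dead]
            mbar = mbar[~dead]
        X = X / mbar
    return X.sum(axis=1)


@dataclass
class ScenarioSpec:
    """Declarative description of one simulation scenario.

    Unset fields (None) resolve to the scenario conventions: intercept
    beta0 = 10 for a continuous outcome and 0 for a binary one, noise
    sd sigma = 1 without covariates and 3 with them, and per-taxon mean
    normalization of the signal sum switched on for the linear/link/
    outlier scenarios (S1/S3/S5) and for random signals in the
    interaction scenario (S4).
    """

    scenario: str = "S1"
    outcome_type: str = "binary"  # "binary" | "continuous"
    signal_type: str = "clustered"  # "clustered" | "random"
    density: float = 0.15
    beta: float = 0.0
    beta0: float | None = None
    sigma: float | None = None
    link: str = "identity"  # "identity" | "log2p1"
    interaction: bool = False
    density2: float = 0.13
    covariate_mode: str = "none"  # "none" | "independent" | "correlated"
    n_outliers: int = 0
    mean_normalize: bool | None = None
    n: int = 50
    p: int = 200
    depth: int = 20000

    def __post_init__(self):
        if self.outcome_type not in ("binary", "continuous"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if self.covariate_mode not in ("none", "independent", "correlated"):
            raise ValueError(f"unknown covariate_mode {self.covariate_mode!r}")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_outliers < 0:
            raise ValueError("n_outliers must be >= 0")

    @property
    def resolved_beta0(self) -> float:
        if self.beta0 is not None:
            return self.beta0
        return 10.0 if self.outcome_type == "continuous" else 0.0

    @property
    def resolved_sigma(self) -> float:
        if self.sigma is not None:
            return self.sigma
        return 1.0 if self.covariate_mode == "none" else 3.0

    @property
    def resolved_mean_normalize(self) -> bool:
        if self.mean_normalize is not None:
            return self.mean_normalize
        if self.interaction:
            return self.signal_type == "random"
        return True

    def to_dict(self) -> dict:
        return asdict(self)


def _covariate(
    community: SyntheticCommunity, spec: ScenarioSpec, rng: np.random.Generator
) -> np.ndarray | None:
    n = community.n_samples
    if spec.covariate_mode == "none":
        return None
    if spec.covariate_mode == "independent":
        return rng.normal(0.0, 1.0, n)
    lin_a = community.lineages.get("A")
    if lin_a is None:
        raise ValueError("correlated covariate needs the registered lineage 'A'")
    return scale(signal_sum(community.table, lin_a.taxa)) + rng.normal(0.0, 1.0, n)


def _assemble_outcome(
    community: SyntheticCommunity,
    term: np.ndarray,
    spec: ScenarioSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    n = community.n_samples
    z = _covariate(community, spec, rng)
    eta = spec.resolved_beta0 + (z if z is not None else 0.0) + term
    if spec.outcome_type == "continuous":
        y = eta + rng.normal(0.0, spec.resolved_sigma, n)
    else:
        y = (rng.random(n) < expit(eta)).astype(np.int64)
    return y, z


def outcome_linear(
    community: SyntheticCommunity,
    signal: Sequence[str],
    spec: ScenarioSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Linear-signal outcome: beta0 + z + beta*scale(signal sum) + noise."""
    if spec.beta != 0 and len(signal) == 0:
        raise ValueError("signal set is empty but beta != 0")
    if spec.beta != 0:
        s = signal_sum(
            community.table, signal,
            mean_normalize=spec.resolved_mean_normalize, on_absent="drop",
        )
        term = spec.beta * scale(s)
    else:
        term = np.zeros(community.n_samples)
    return _assemble_outcome(community, term, spec, rng)


def outcome_nonlinear(
    community: SyntheticCommunity,
    signal: Sequence[str],
    spec: ScenarioSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    """As :func:`outcome_linear` with x replaced by log2(x+1) in the sum."""
    if spec.beta != 0 and len(signal) == 0:
        raise ValueError("signal set is empty but beta != 0")
    if spec.beta != 0:
        s = signal_sum(
            community.table,
            signal,
            link="log2p1",
            mean_normalize=spec.resolved_mean_normalize,
            on_absent="drop",
        )
        term = spec.beta * scale(s)
    else:
        term = np.zeros(community.n_samples)
    return _assemble_outcome(community, term, spec, rng)


def outcome_interaction(
    community: SyntheticCommunity,
    signal: Sequence[str],
    signal2: Sequence[str],
    spec: ScenarioSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Pure product interaction between two disjoint signal sets.

    The signal term is beta * scale(sum over S) * scale(sum over S'),
    so each factor alone is (marginally) uncorrelated with the outcome.
    """
    if set(signal) & set(signal2):
        raise ValueError("interaction signal sets must be disjoint")
    if spec.beta != 0:
        mn = spec.resolved_mean_normalize
        f1 = scale(signal_sum(community.table, signal, mean_normalize=mn, on_absent="drop"))
        f2 = scale(signal_sum(community.table, signal2, mean_normalize=mn, on_absent="drop"))
        term = spec.beta * f1 * f2
    else:
        term = np.zeros(community.n_samples)
    return _assemble_outcome(community, term, spec, rng)


def inject_outliers(
    community: SyntheticCommunity, k: int, rng: np.random.Generator
) -> SyntheticCommunity:
    """Shuffle the taxon order of k uniformly chosen samples.

    Each corrupted sample keeps its multiset of counts (and its total
    depth) but loses any relation between counts and taxon identity —
    a sample with a wholesale different profile.
    """
    n = community.n_samples
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}]")
    if k == 0:
        return community
    table = community.table.copy()
    rows = rng.choice(n, size=k, replace=False)
    values = table.to_numpy().copy()
    for i in rows:
        values[i, :] = values[i, rng.permutation(values.shape[1])]
    table.iloc[:, :] = values
    return SyntheticCommunity(
        table=table,
        tree=community.tree,
        lineages=community.lineages,
        depth=community.depth,
        base_proportions=community.base_proportions,
    )


# ----------------------------------------------------------------------
# scenario driver


@dataclass
class SimulatedDataset:
    """One simulated dataset ready for testing."""

    table: pd.DataFrame
    tree: PhyloTree
    y: np.ndarray
    covariates: pd.DataFrame | None
    community: SyntheticCommunity
    signal: tuple[str, ...]
    signal2: tuple[str, ...] = ()


def simulate_dataset(spec: ScenarioSpec, seed=None) -> SimulatedDataset:
    """Generate community + outcome for one scenario replicate."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_comm, s_sig, s_out = ss.spawn(3)
    community = synth_community(spec.n, spec.p, spec.depth, seed=s_comm)
    need_signal = spec.beta != 0
    signal: tuple[str, ...] = ()
    signal2: tuple[str, ...] = ()
    if need_signal:
        sig_seed = int(s_sig.generate_state(1)[0])
        signal = select_signal_set(community, spec.signal_type, spec.density, sig_seed)
        if spec.interaction:
            if spec.signal_type == "clustered":
                lin_c = community.lineages.get("C")
                if lin_c is None:
                    raise ValueError("interaction scenario needs lineage 'C'")
                signal2 = lin_c.taxa
            else:
                pool = [t for t in community.taxa if t not in set(signal)]
                k2 = max(1, round(spec.density2 * spec.p))
                perm = np.random.default_rng(sig_seed + 1).permutation(len(pool))
                signal2 = tuple(pool[i] for i in perm[:k2])
    rng = np.random.default_rng(s_out)
    if spec.interaction and need_signal:
        y, z = outcome_interaction(community, signal, signal2, spec, rng)
    elif spec.link == "log2p1":
        y, z = outcome_nonlinear(community, signal, spec, rng)
    else:
        y, z = outcome_linear(community, signal, spec, rng)
    if spec.n_outliers:
        community = inject_outliers(community, spec.n_outliers, rng)
    Z = (
        pd.DataFrame({"z": z}, index=community.table.index)
        if z is not None
        else None
    )
    return SimulatedDataset(
        table=community.table,
        tree=community.tree,
        y=y,
        covariates=Z,
        community=community,
        signal=signal,
        signal2=signal2,
    )


@dataclass
class SimulationResult:
    """Rejection-rate estimate over Monte-Carlo scenario replicates."""

    spec: ScenarioSpec
    n_runs: int
    alpha: float
    p_values: np.ndarray
    rejection_rate: float
    ci_low: float
    ci_high: float
    seed: int | None
    config: dict

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "n_runs": self.n_runs,
            "alpha": self.alpha,
            "p_values": [float(v) for v in self.p_values],
            "rejection_rate": self.rejection_rate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "seed": self.seed,
            "config": self.config,
        }


def estimate_error_rate(
    spec: ScenarioSpec,
    n_runs: int,
    B: int = 99,
    alpha: float = 0.05,
    config: ForestConfig | None = None,
    seed=None,
    use_tree: bool = True,
    max_sparsity: float = 0.96,
) -> SimulationResult:
    """Empirical rejection fraction of the test over scenario replicates.

    Under a beta = 0 spec this estimates the type-I error rate; under a
    signal spec it estimates power. Each replicate draws a fresh
    community and outcome from independently spawned seeds and runs the
    full pipeline. The Wilson 95% confidence interval accompanies the
    point estimate. ``use_tree=False`` ablates the phylogenetic features
    (leaf columns only).
    """
    if n_runs < 20:
        raise ValueError("n_runs must be >= 20 for a meaningful rate estimate")
    if config is None:
        config = ForestConfig()
    pvals = np.empty(n_runs)
    children = np.random.SeedSequence(seed).spawn(n_runs)
    for r, child in enumerate(children):
        s_data, s_test = child.spawn(2)
        ds = simulate_dataset(spec, seed=s_data)
        res = rftest(
            ds.table,
            ds.y,
            tree=ds.tree if use_tree else None,
            covariates=ds.covariates,
            n_permutations=B,
            n_trees=config.n_trees,
            mtry_fraction=config.mtry_fraction,
            n_repeats=config.n_repeats,
            min_node_size=config.min_node_size,
            max_sparsity=max_sparsity,
            outcome_type=spec.outcome_type,
            random_state=int(s_test.generate_state(1)[0]),
        )
        pvals[r] = res.p_value
    k = int(np.sum(pvals <= alpha))
    lo, hi = proportion_confint(k, n_runs, alpha=0.05, method="wilson")
    return SimulationResult(
        spec=spec,
        n_runs=n_runs,
        alpha=alpha,
        p_values=pvals,
        rejection_rate=k / n_runs,
        ci_low=float(lo),
        ci_high=float(hi),
        seed=seed if seed is None or isinstance(seed, int) else None,
        config=config.to_dict(),
    )
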