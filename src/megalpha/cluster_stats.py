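"""Spatial cluster-based permutation statistics for within-subject designs.

The inference chain: per-element (sensor or source vertex) repeated-measures
F statistics, thresholding at the F value of a one-tail p = 0.05, grouping
of supra-threshold spatially adjacent elements into clusters scored by their
summed F ("mass"), and a Monte-Carlo family-wise test comparing each
observed mass against the permutation distribution of the *maximal* cluster
mass under within-subject label shuffling.

Permutation schemes
-------------------
* Main effects of 2-level factors: the factor's two levels are swapped
  independently per subject (uniform over the 2**n sign-flips of the
  per-subject contrast).  On designs small enough that all sign patterns
  can be enumerated, the test switches to exhaustive enumeration and the
  p value is exact.
* Interactions: by default the full set of design-cell labels is permuted
  within each subject and the F map recomputed; the sign-flip subgroup
  scheme is available via ``PermutationConfig.interaction_scheme``.

Subjects are never exchanged with each other — only labels within a subject
move, so no between-subject exchangeability is assumed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.stats


@dataclass(frozen=True)
class DesignSpec:
    """Complete crossed within-subject factorial design.

    ``factors`` is an ordered list of (name, levels); the design-cell axis
    of a data array enumerates the Cartesian product of levels in this
    order, last factor fastest (``itertools.product`` order).
    """

    factors: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("design needs at least one factor")
        for name, levels in self.factors:
            if len(levels) < 2:
                raise ValueError(f"factor {name!r} needs >= 2 levels")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.factors)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(levels) for _, levels in self.factors)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def cells(self) -> list[tuple[str, ...]]:
        return list(itertools.product(*(levels for _, levels in self.factors)))

    def axis_of(self, factor: str) -> int:
        try:
            return self.names.index(factor)
        except ValueError:
            raise ValueError(f"unknown factor {factor!r}; design has {self.names}")


@dataclass(frozen=True)
class FMap:
    """Per-element F statistics for one effect of a within-subject design."""

    f_values: np.ndarray  # (n_elements,)
    df_effect: int
    df_error: int
    effect: tuple[str, ...]


@dataclass(frozen=True)
class ClusterResult:
    """A spatially contiguous supra-threshold element set with its F mass."""

    members: tuple[int, ...]
    mass: float
    p_monte_carlo: float | None = None
    effect: str = ""
    threshold: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the max-cluster-mass permutation test."""

    n_permutations: int = 1000
    cluster_alpha: float = 0.05  # one-tail p of the cluster-forming F threshold
    final_alpha: float = 0.05
    seed: int = 0
    p_estimator: str = "add_one"  # or "strict_percentile"
    interaction_scheme: str = "cell_permutation"  # or "sign_flip"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        for a in (self.cluster_alpha, self.final_alpha):
            if not 0 < a < 1:
                raise ValueError("alphas must lie in (0, 1)")
        if self.p_estimator not in ("add_one", "strict_percentile"):
            raise ValueError(f"unknown p_estimator {self.p_estimator!r}")


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def _effect_term(grid: np.ndarray, axes: tuple[int, ...], all_axes: tuple[int, ...]):
    """Inclusion-exclusion effect term for the factor subset ``axes``.

    ``grid`` has shape (n_subj, l1, ..., lk, n_elem); ``axes`` indexes the
    factor dimensions (1..k) and may include 0 (the subject axis).  Returns
    the effect estimate broadcast to grid shape.
    """
    term = np.zeros_like(grid)
    for r in range(len(axes) + 1):
        for sub in itertools.combinations(axes, r):
            avg_over = tuple(a for a in all_axes if a not in sub)
            marg = grid.mean(axis=avg_over, keepdims=True)
            term = term + (-1) ** (len(axes) - r) * marg
    return term


def rm_anova_f_map(
    data: np.ndarray, design: DesignSpec, effect: str | tuple[str, ...]
) -> FMap:
    """Univariate repeated-measures F per element for one effect.

    Parameters
    ----------
    data : (n_subjects, n_cells, n_elements) array
        Complete balanced within-subject data; the cell axis follows
        ``design.cells()`` order.
    effect : factor name or tuple of names (interaction).

    Notes
    -----
    F = MS_effect / MS_(effect x subject): the error term for each
    within-subject effect is its interaction with subject.  Computed by
    inclusion-exclusion over marginal means, which is exact for complete
    balanced designs.
    """
    if isinstance(effect, str):
        effect = (effect,)
    data = np.asarray(data, dtype=float)
    n_subj, n_cells, n_elem = data.shape
    if n_subj < 2:
        raise ValueError("need >= 2 subjects")
    if n_cells != design.n_cells:
        raise ValueError(
            f"data has {n_cells} cells but the design defines {design.n_cells}"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values (incomplete design?)")

    grid = data.reshape(n_subj, *design.shape, n_elem)
    k = len(design.factors)
    eff_axes = tuple(sorted(design.axis_of(name) + 1 for name in effect))
    err_axes = tuple(sorted((0,) + eff_axes))
    all_axes = tuple(range(k + 1))  # subject + factors; element axis excluded

    eff_term = _effect_term(grid, eff_axes, all_axes)
    err_term = _effect_term(grid, err_axes, all_axes)

    # SS = sum over the full grid of the (broadcast) squared term
    ss_eff = (eff_term**2).sum(axis=tuple(range(k + 1)))
    ss_err = (err_term**2).sum(axis=tuple(range(k + 1)))

    df_eff = int(np.prod([design.shape[a - 1] - 1 for a in eff_axes]))
    df_err = (n_subj - 1) * df_eff

    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    f = np.zeros(n_elem)
    ok = ms_err > 0
    f[ok] = ms_eff[ok] / ms_err[ok]
    # degenerate separation: effect variance with zero error
    f[~ok & (ms_eff > 0)] = np.finfo(float).max
    return FMap(f_values=f, df_effect=df_eff, df_error=df_err, effect=tuple(effect))


def paired_f_map(x: np.ndarray, y: np.ndarray) -> FMap:
    """Two-level within-subject F (squared paired t) per element.

    ``x`` and ``y`` are (n_subjects, n_elements) arrays of the same
    subjects in the same order (e.g. baseline-corrected real vs sham power).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    d = x - y
    mean = d.mean(axis=0)
    var = d.var(axis=0, ddof=1)
    f = np.zeros(d.shape[1])
    ok = var > 0
    f[ok] = n * mean[ok] ** 2 / var[ok]
    f[~ok & (mean != 0)] = np.finfo(float).max
    return FMap(f_values=f, df_effect=1, df_error=n - 1, effect=("exposure",))


def paired_oneway_f_map(
    real: pd.DataFrame, sham: pd.DataFrame, value: str = "log_power"
) -> FMap:
    """Real-vs-sham one-way within-subject F map from long-format tables.

    Both inputs must hold one row per (subject, sensor) — e.g. a single
    baseline-corrected run and eyes condition — with identical subjects and
    sensors.
    """
    piv_r = real.pivot_table(index="subject", columns="sensor", values=value)
    piv_s = sham.pivot_table(index="subject", columns="sensor", values=value)
    if not piv_r.index.equals(piv_s.index):
        raise ValueError("subject sets differ between real and sham inputs")
    if not piv_r.columns.equals(piv_s.columns):
        raise ValueError("sensor sets differ between real and sham inputs")
    return paired_f_map(piv_r.to_numpy(), piv_s.to_numpy())


# ---------------------------------------------------------------------------
# clustering


def _adjacency_edges(adjacency: np.ndarray) -> np.ndarray:
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    iu = np.triu_indices(adjacency.shape[0], k=1)
    mask = adjacency[iu].astype(bool)
    return np.column_stack([iu[0][mask], iu[1][mask]])


def _components(mask: np.ndarray, edges: np.ndarray) -> list[np.ndarray]:
    """Connected components of the masked vertex set (union-find)."""
    nodes = np.flatnonzero(mask)
    if nodes.size == 0:
        return []
    parent = {int(v): int(v) for v in nodes}

    def find(v: int) -> int:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        a, b = int(a), int(b)
        if mask[a] and mask[b]:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for v in nodes:
        groups.setdefault(find(int(v)), []).append(int(v))
    return [np.array(sorted(g)) for g in groups.values()]


def form_clusters(
    fmap: FMap | np.ndarray,
    threshold: float,
    adjacency: np.ndarray,
    effect: str = "",
) -> list[ClusterResult]:
    """Connected components of supra-threshold elements, scored by F mass.

    Elements enter a cluster iff their F strictly exceeds ``threshold``
    ("exceeded a threshold"); clusters are returned in descending mass
    order (ties broken by smallest member index).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    f = fmap.f_values if isinstance(fmap, FMap) else np.asarray(fmap, dtype=float)
    mask = f > threshold
    comps = _components(mask, _adjacency_edges(adjacency))
    clusters = [
        ClusterResult(
            members=tuple(int(i) for i in comp),
            mass=float(f[comp].sum()),
            effect=effect,
            threshold=float(threshold),
        )
        for comp in comps
    ]
    clusters.sort(key=lambda c: (-c.mass, c.members))
    return clusters


def _max_mass(f: np.ndarray, threshold: float, edges: np.ndarray) -> float:
    mask = f > threshold
    comps = _components(mask, edges)
    if not comps:
        return 0.0
    return max(float(f[c].sum()) for c in comps)


def forming_threshold(df_effect: int, df_error: int, cluster_alpha: float) -> float:
    """Cluster-forming F threshold: upper-tail quantile at the one-tail alpha."""
    return float(scipy.stats.f.ppf(1.0 - cluster_alpha, df_effect, df_error))


# ---------------------------------------------------------------------------
# permutation tests


def _sign_flip_f(contrasts: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """F maps for many sign-flip patterns at once.

    ``contrasts``: (n_subj, n_elem) per-subject contrast scores; ``signs``:
    (n_perm, n_subj) of +-1.  Uses the identity that the per-subject squared
    contrast is sign-invariant, so only the mean changes per permutation.
    """
    n = contrasts.shape[0]
    sumsq = (contrasts**2).sum(axis=0)  # (n_elem,)
    means = signs @ contrasts / n  # (n_perm, n_elem)
    var = (sumsq[None, :] - n * means**2) / (n - 1)
    f = np.zeros_like(means)
    ok = var > 0
    f[ok] = n * means[ok] ** 2 / var[ok]
    f[~ok & (means != 0)] = np.finfo(float).max
    return f


def _monte_carlo_p(
    observed_mass: float, null_max: np.ndarray, estimator: str, exhaustive: bool
) -> float:
    if exhaustive:
        # exact enumeration: the identity relabelling is one of the patterns
        return float((null_max >= observed_mass).mean())
    n = len(null_max)
    count = int((null_max >= observed_mass).sum())
    if estimator == "add_one":
        return (1 + count) / (1 + n)
    return count / n


def paired_cluster_test(
    x: np.ndarray,
    y: np.ndarray,
    adjacency: np.ndarray,
    config: PermutationConfig | None = None,
    effect: str = "exposure",
) -> list[ClusterResult]:
    """Max-cluster-mass permutation test for a paired two-condition contrast.

    ``x`` and ``y`` are (n_subjects, n_elements) condition values for the
    same subjects.  The null is generated by swapping the two condition
    labels independently per subject (sign-flipping the paired difference);
    if all 2**n patterns fit within ``n_permutations`` the test enumerates
    them exhaustively and the p values are exact.
    """
    config = config or PermutationConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    n_subj = x.shape[0]
    if n_subj < 2:
        raise ValueError("need >= 2 subjects")
    contrasts = x - y
    threshold = forming_threshold(1, n_subj - 1, config.cluster_alpha)
    edges = _adjacency_edges(adjacency)

    # the observed F map is row 0 of the same matrix product as the permuted
    # maps, so the identity relabelling reproduces it bit-exactly (a separate
    # 1-row product can differ in the last bit and bias exhaustive p values)
    exhaustive = 2**n_subj <= config.n_permutations
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n_subj)))
    else:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        signs = np.vstack(
            [
                np.ones(n_subj),
                rng.choice([1.0, -1.0], size=(config.n_permutations, n_subj)),
            ]
        )
    f_all = _sign_flip_f(contrasts, signs)
    f_obs = f_all[0]  # identity: itertools.product starts with all +1
    f_perm = f_all if exhaustive else f_all[1:]
    clusters = form_clusters(f_obs, threshold, adjacency, effect=effect)
    if not clusters:
        return []
    null_max = np.array([_max_mass(f, threshold, edges) for f in f_perm])

    return [
        replace(
            c,
            p_monte_carlo=_monte_carlo_p(
                c.mass, null_max, config.p_estimator, exhaustive
            ),
        )
        for c in clusters
    ]


def _contrast_scores(
    data: np.ndarray, design: DesignSpec, effect: tuple[str, ...]
) -> np.ndarray:
    """Per-subject contrast scores for an effect of 2-level factors.

    For a main effect: difference of the factor's level means (other factors
    averaged).  For interactions: the +-1 product-coded contrast.  The
    within-subject F of the effect equals the squared one-sample t of these
    scores.
    """
    n_subj, n_cells, n_elem = data.shape
    codes = np.ones(n_cells)
    for ci, cell in enumerate(design.cells()):
        for name in effect:
            ax = design.axis_of(name)
            levels = dict(self_levels(design))[name]
            codes[ci] *= 1.0 if cell[ax] == levels[0] else -1.0
    # normalise so the score is a difference of cell-group means
    scale = 2.0 / n_cells
    return np.einsum("c,sce->se", codes * scale, data)


def self_levels(design: DesignSpec) -> list[tuple[str, tuple[str, ...]]]:
    return [(name, levels) for name, levels in design.factors]


def cluster_permutation_test(
    data: np.ndarray,
    design: DesignSpec,
    effect: str | tuple[str, ...],
    adjacency: np.ndarray,
    config: PermutationConfig | None = None,
) -> list[ClusterResult]:
    """Cluster permutation test for one effect of a within-subject factorial.

    ``data``: (n_subjects, n_cells, n_elements), cells in ``design.cells()``
    order.  Main effects of 2-level factors use per-subject level swaps
    (sign-flips, exact for small n); interactions permute the full set of
    design-cell labels within each subject and recompute the repeated-
    measures F map per permutation (or sign-flip the interaction contrast
    when ``config.interaction_scheme == "sign_flip"``).
    """
    config = config or PermutationConfig()
    if isinstance(effect, str):
        effect = (effect,)
    data = np.asarray(data, dtype=float)
    n_subj, n_cells, n_elem = data.shape
    for name in effect:
        ax = design.axis_of(name)
        if design.shape[ax] != 2:
            raise NotImplementedError(
                "permutation clustering is implemented for 2-level factors"
            )

    observed = rm_anova_f_map(data, design, effect)
    threshold = forming_threshold(observed.df_effect, observed.df_error,
                                  config.cluster_alpha)
    edges = _adjacency_edges(adjacency)

    use_sign_flip = len(effect) == 1 or config.interaction_scheme == "sign_flip"
    if use_sign_flip:
        # observed F map is row 0 of the same matrix product as the permuted
        # maps (see paired_cluster_test for the bit-exactness rationale)
        contrasts = _contrast_scores(data, design, effect)
        exhaustive = 2**n_subj <= config.n_permutations
        if exhaustive:
            signs = np.array(list(itertools.product((1.0, -1.0), repeat=n_subj)))
        else:
            rng = np.random.default_rng(np.random.SeedSequence(config.seed))
            signs = np.vstack(
                [
                    np.ones(n_subj),
                    rng.choice([1.0, -1.0],
                               size=(config.n_permutations, n_subj)),
                ]
            )
        f_all = _sign_flip_f(contrasts, signs)
        f_obs = f_all[0]
        f_perm = f_all if exhaustive else f_all[1:]
        clusters = form_clusters(f_obs, threshold, adjacency,
                                 effect="x".join(effect))
        if not clusters:
            return []
        null_max = np.array([_max_mass(f, threshold, edges) for f in f_perm])
    else:
        clusters = form_clusters(observed, threshold, adjacency,
                                 effect="x".join(effect))
        if not clusters:
            return []
        exhaustive = False
        null_max = np.empty(config.n_permutations)
        for pi in range(config.n_permutations):
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, pi]))
            shuffled = np.empty_like(data)
            for si in range(n_subj):
                shuffled[si] = data[si, rng.permutation(n_cells)]
            fmap = rm_anova_f_map(shuffled, design, effect)
            null_max[pi] = _max_mass(fmap.f_values, threshold, edges)

    return [
        replace(
            c,
            p_monte_carlo=_monte_carlo_p(
                c.mass, null_max, config.p_estimator, exhaustive
            ),
        )
        for c in clusters
    ]


# ---------------------------------------------------------------------------
# long-format helpers


def to_cell_array(
    dataset: pd.DataFrame,
    design: DesignSpec,
    value: str = "log_power",
    element: str = "sensor",
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Pivot a long-format PowerDataset into (subjects, cells, elements).

    The dataset must contain one row per subject x design cell x element;
    design factor names must be columns.  Returns (array, subjects,
    elements).
    """
    cols = list(design.names)
    piv = dataset.pivot_table(
        index="subject", columns=cols + [element], values=value, sort=True
    )
    subjects = list(piv.index)
    elements = np.array(sorted(dataset[element].unique()))
    n_elem = len(elements)
    cells = design.cells()
    arr = np.full((len(subjects), len(cells), n_elem), np.nan)
    for ci, cell in enumerate(cells):
        for ei, el in enumerate(elements):
            key = (*cell, el) if len(cols) > 1 else (cell[0], el)
            try:
                arr[:, ci, ei] = piv[key].to_numpy()
            except KeyError:
                raise ValueError(f"missing design cell {cell} for element {el}")
    if np.isnan(arr).any():
        raise ValueError("incomplete design: NaN cells after pivoting")
    return arr, subjects, elements
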