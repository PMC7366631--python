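"""Variable engineering: PCA feature extraction, SPA and GA wavelength selection.

All three engines operate on preprocessed, replicate-averaged spectra and
see only the training and validation sets — never the test rows.

*PCA* extracts orthogonal score directions of maximal variance; the few
leading scores replace the full spectrum as classifier input.

*SPA* (successive projections algorithm) is forward selection that fights
collinearity: starting from each wavenumber in turn it grows a chain in
which every next variable has the largest norm after projection onto the
orthogonal complement of the chain so far; every chain prefix is a
candidate subset and the one with the lowest validation misclassification
under an LDA fit wins.

*GA* evolves binary masks over the wavenumber columns: tournament
selection, one-point crossover, per-gene bit-flip mutation and elitism,
with fitness = validation accuracy of an LDA on the masked variables
minus a parsimony penalty proportional to the mask size, so compact
marker sets are favoured without a hard cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .classify import fit_discriminant, predict_discriminant
from .dataset import SpectrumSet
from .exceptions import ConfigurationError


@dataclass
class PCAResult:
    """Column-mean-centered principal component decomposition."""

    scores: np.ndarray  # (n, k)
    loadings: np.ndarray  # (k, p), rows orthonormal
    explained_variance_fraction: np.ndarray  # (k,), non-increasing
    mean_spectrum: np.ndarray  # (p,)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new rows onto the fitted components."""
        return (np.atleast_2d(X) - self.mean_spectrum) @ self.loadings.T


@dataclass
class FeatureSelectionResult:
    """Outcome of SPA or GA selection (or a PCA summary)."""

    selected_indices: np.ndarray  # unique, sorted column indices
    selected_wavenumbers: np.ndarray  # cm^-1, consistent with indices
    cost: float  # validation criterion at the optimum
    method: str  # "PCA" | "SPA" | "GA"
    trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        if len(np.unique(self.selected_indices)) != self.selected_indices.size:
            raise ValueError("selected indices must be unique")
        self.selected_indices = np.sort(self.selected_indices)


def pca_decompose(X: np.ndarray, n_components: int) -> PCAResult:
    """Mean-centered PCA with a deterministic sign convention.

    Each loading is flipped so its largest-magnitude entry is positive.
    If the data rank is below ``n_components`` the decomposition is
    truncated to the rank, with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, columns)={min(n - 1, p)}"
        )
    fit = PCA(n_components=n_components, svd_solver="full").fit(X)
    loadings = fit.components_
    scores = fit.transform(X)
    frac = fit.explained_variance_ratio_

    total_var = fit.explained_variance_.sum()
    keep = fit.explained_variance_ > 1e-12 * max(total_var, 1e-300)
    if not keep.all():
        warnings.warn(
            f"data rank {int(keep.sum())} < requested {n_components} components; truncating",
            RuntimeWarning,
            stacklevel=2,
        )
        loadings, scores, frac = loadings[keep], scores[:, keep], frac[keep]

    flip = np.sign(loadings[np.arange(loadings.shape[0]), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    return PCAResult(
        scores=scores * flip,
        loadings=loadings * flip[:, None],
        explained_variance_fraction=frac,
        mean_spectrum=fit.mean_,
    )


def choose_n_components(result: PCAResult, threshold: float, cap: int = 10) -> int:
    """Smallest k whose cumulative explained fraction reaches `threshold` (capped)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cum = np.cumsum(result.explained_variance_fraction)
    reached = np.nonzero(cum >= threshold - 1e-12)[0]
    k = int(reached[0]) + 1 if reached.size else cum.size
    return min(k, cap)


def _validation_error(
    X_train: np.ndarray, y_train, X_val: np.ndarray, y_val, cols: np.ndarray
) -> float:
    """Validation misclassification fraction of an LDA on the given columns."""
    model = fit_discriminant(X_train[:, cols], y_train)
    pred = predict_discriminant(X_val[:, cols], model, rule="lda")
    return float(np.mean(pred != np.asarray(y_val)))


def spa_projection_chain(Xc: np.ndarray, start: int, max_vars: int) -> list:
    """Successive-projection chain of column indices from a starting column.

    At each step the next column is the one with the largest residual norm
    after projecting out the span of the columns already in the chain
    (computed on the centered matrix ``Xc``; ties break to the lower index).
    """
    n, p = Xc.shape
    R = Xc.copy()
    chain = [start]
    for _ in range(min(max_vars, p) - 1):
        q = R[:, chain[-1]]
        nq = np.linalg.norm(q)
        if nq < 1e-12:
            break
        q = q / nq
        R = R - np.outer(q, q @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        if norms.max() < 1e-10:
            break
        chain.append(int(np.argmax(norms)))
    return chain


def spa_select(train: SpectrumSet, val: SpectrumSet, max_vars: int) -> FeatureSelectionResult:
    """SPA wavelength selection scored by LDA validation error.

    Chains are grown from every starting column (deterministic — no RNG);
    every chain prefix is a candidate subset; the candidate with the
    lowest validation misclassification wins, ties going to fewer
    variables and then to the earlier candidate in scan order.
    """
    Xtr, ytr = train.absorbance, train.label
    Xval, yval = val.absorbance, val.label
    n, p = Xtr.shape
    if max_vars > min(n - 2, p):
        raise ValueError(f"max_vars={max_vars} exceeds min(train rows - 2, columns)={min(n - 2, p)}")
    Xc = Xtr - Xtr.mean(axis=0)
    col_norms = np.linalg.norm(Xc, axis=0)

    cache: dict = {}
    best = None  # (cost, n_vars, order, subset)
    trace = []
    order = 0
    for start in range(p):
        if col_norms[start] < 1e-12:
            warnings.warn(f"skipping degenerate (zero-variance) column {start}", RuntimeWarning)
            continue
        chain = spa_projection_chain(Xc, start, max_vars)
        for k in range(1, len(chain) + 1):
            subset = np.sort(chain[:k])
            key = subset.tobytes()
            if key in cache:
                cost = cache[key]
            else:
                cost = _validation_error(Xtr, ytr, Xval, yval, subset)
                cache[key] = cost
            trace.append({"start": start, "n_vars": k, "cost": cost})
            cand = (cost, k, order, subset)
            if best is None or cand[:3] < best[:3]:
                best = cand
            order += 1
    if best is None:
        raise ValueError("all columns are degenerate; nothing to select")
    cost, _, _, subset = best
    return FeatureSelectionResult(
        selected_indices=subset,
        selected_wavenumbers=train.axis[subset],
        cost=cost,
        method="SPA",
        trace=trace,
    )


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters (package defaults; tournament size 2).

    ``parsimony_weight`` is the soft feature cap: fitness = validation
    accuracy - parsimony_weight * (n_selected / n_columns).  ``init_prob``
    is the per-gene activation probability of the initial population.
    """

    population: int = 40
    generations: int = 100
    crossover_prob: float = 0.6
    mutation_prob: float = 0.01
    elitism: int = 1
    parsimony_weight: float = 0.05
    init_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 4 or self.population % 2:
            raise ConfigurationError("population: must be even and >= 4")
        if self.generations < 1:
            raise ConfigurationError("generations: must be >= 1")
        for name in ("crossover_prob", "mutation_prob", "init_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name}: must be in [0, 1]")
        if not 0 <= self.elitism < self.population:
            raise ConfigurationError("elitism: must be in [0, population)")


def ga_select(train: SpectrumSet, val: SpectrumSet, config: GAConfig | None = None) -> FeatureSelectionResult:
    """GA wavelength selection over binary masks, scored by LDA validation accuracy.

    Fully reproducible from ``config.seed``; the best-ever fitness is
    non-decreasing across generations (elitism).  Returns the best-ever
    chromosome with ``cost = 1 - fitness``.
    """
    config = config or GAConfig()
    Xtr, ytr = train.absorbance, np.asarray(train.label)
    Xval, yval = val.absorbance, np.asarray(val.label)
    for name, y in (("train", ytr), ("validation", yval)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} set must contain both classes")
    p = Xtr.shape[1]
    rng = np.random.default_rng(config.seed)

    cache: dict = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            if not mask.any():
                cache[key] = -np.inf  # an empty chromosome is never viable
            else:
                cols = np.nonzero(mask)[0]
                acc = 1.0 - _validation_error(Xtr, ytr, Xval, yval, cols)
                cache[key] = acc - config.parsimony_weight * cols.size / p
        return cache[key]

    pop = rng.random((config.population, p)) < config.init_prob
    for chrom in pop:  # guarantee no dead chromosomes at start
        if not chrom.any():
            chrom[rng.integers(p)] = True

    best_mask, best_fit = None, -np.inf
    trace = []
    for gen in range(config.generations):
        fits = np.array([fitness(c) for c in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()
        trace.append(
            {
                "generation": gen,
                "population": len(pop),
                "best_fitness": best_fit,
                "mean_fitness": float(np.mean(fits[np.isfinite(fits)])) if np.isfinite(fits).any() else -np.inf,
                "best_n_vars": int(best_mask.sum()),
            }
        )
        if gen == config.generations - 1:
            break
        elite_idx = np.argsort(-fits, kind="stable")[: config.elitism]
        children = [pop[i].copy() for i in elite_idx]
        while len(children) < config.population:
            parents = []
            for _ in range(2):  # tournament of size 2
                a, b = rng.integers(config.population, size=2)
                parents.append(pop[a] if fits[a] >= fits[b] else pop[b])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if rng.random() < config.crossover_prob and p > 1:
                cut = int(rng.integers(1, p))
                c1[cut:], c2[cut:] = parents[1][cut:], parents[0][cut:]
            for c in (c1, c2):
                flip = rng.random(p) < config.mutation_prob
                c[flip] = ~c[flip]
            children.extend([c1, c2])
        pop = np.array(children[: config.population])

    cols = np.nonzero(best_mask)[0]
    return FeatureSelectionResult(
        selected_indices=cols,
        selected_wavenumbers=train.axis[cols],
        cost=1.0 - best_fit,
        method="GA",
        trace=trace,
    )
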