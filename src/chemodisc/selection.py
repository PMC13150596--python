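"""Variable selection for discriminant spectra: SPA and GA driving LDA cost.

Full-spectrum LDA is singular when variables outnumber samples, so a small
discriminant subset of wavelengths/wavenumbers is searched for:

* **SPA** (successive projections algorithm) -- deterministic.  Starting
  from each column in turn it grows a chain by repeatedly appending the
  column with the largest norm of its projection onto the orthogonal
  complement of the chain's span (minimal collinearity).  Every chain
  prefix of size 1..max_vars is scored and the cheapest subset wins.
* **GA** -- a seeded evolutionary search over index subsets of size
  <= max_vars (default caps at 10 variables), with tournament selection,
  uniform-exchange crossover, per-gene mutation and single elitism.

Both use the same cost: leave-one-out LDA misclassification fraction on the
training partition.  Final ties break toward fewer variables (parsimony),
then the smaller start index.

Fisher weights rank each selected variable's univariate discriminant power,
``(mean_A - mean_B)^2 / (var_A + var_B)``, attributed to the class with the
larger mean -- the per-band class attribution shown alongside selected
variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discriminant import loo_cv

__all__ = [
    "SPAConfig",
    "GAConfig",
    "SelectionResult",
    "RankError",
    "spa_chain",
    "spa_select",
    "ga_select",
    "fisher_weights",
    "loo_cost",
]

_RESIDUAL_TOL = 1e-10


class RankError(np.linalg.LinAlgError):
    """SPA chain exhausted the attainable column rank."""

    def __init__(self, msg: str, chain: list[int]):
        super().__init__(msg)
        self.chain = chain


@dataclass
class SPAConfig:
    """Candidate subset sizes 1..max_vars are all evaluated."""

    max_vars: int = 10

    def __post_init__(self) -> None:
        if self.max_vars < 1:
            raise ValueError("max_vars must be >= 1")


@dataclass
class GAConfig:
    population: int = 100
    generations: int = 100
    mutation_rate: float = 0.05
    crossover_rate: float = 0.60
    max_vars: int = 10
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for name in ("mutation_rate", "crossover_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.max_vars < 1:
            raise ValueError("max_vars must be >= 1")


@dataclass
class SelectionResult:
    selected_indices: list[int]
    cost: float
    trace: list[float]
    method: str
    extras: dict = field(default_factory=dict)

    def to_dict(self, axis: np.ndarray | None = None) -> dict:
        d = {
            "method": self.method,
            "selected_indices": list(self.selected_indices),
            "cost": self.cost,
            "trace": list(self.trace),
        }
        if axis is not None:
            d["selected_axis_values"] = [float(axis[i]) for i in self.selected_indices]
        return d


def loo_cost(X: np.ndarray, y, indices) -> float:
    """Leave-one-out LDA misclassification fraction on the given columns."""
    counts, _ = loo_cv(X, y, list(indices))
    return (counts.FP + counts.FN) / counts.total


class _CostCache:
    """Memoised LOO cost: a pure function of the sorted index tuple."""

    def __init__(self, X: np.ndarray, y):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray([str(c) for c in y])
        self._cache: dict[tuple, float] = {}

    def __call__(self, indices) -> float:
        key = tuple(sorted(int(i) for i in indices))
        if key not in self._cache:
            self._cache[key] = loo_cost(self.X, self.y, key)
        return self._cache[key]


# -- SPA -------------------------------------------------------------------


def spa_chain(matrix: np.ndarray, start: int, m: int) -> list[int]:
    """Successive-projections chain of ``m`` column indices from ``start``.

    Gram-Schmidt style: at each step every remaining column is projected
    onto the orthogonal complement of the span of the chosen columns and the
    one with maximal residual norm is appended (ties -> smallest index).
    Columns whose residual norm falls below tolerance are ineligible; if no
    eligible column remains before reaching ``m`` a :class:`RankError`
    carrying the attained chain is raised.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = X.shape
    if not 0 <= start < p:
        raise ValueError(f"start column {start} out of range")
    if not 1 <= m <= min(n - 1, p):
        raise ValueError(f"chain length m={m} out of range [1, {min(n - 1, p)}]")
    R = X.copy()  # residuals of every column w.r.t. the chosen span
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    chain = [int(start)]
    for _ in range(m - 1):
        v = R[:, chain[-1]].copy()
        nv = np.linalg.norm(v)
        if nv < _RESIDUAL_TOL:
            raise RankError(f"rank exhausted at chain length {len(chain)}", chain)
        v /= nv
        R = R - np.outer(v, v @ R)
        norms = np.linalg.norm(R, axis=0)
        eligible = norms / scale >= _RESIDUAL_TOL
        eligible[chain] = False
        if not np.any(eligible):
            raise RankError(f"rank exhausted at chain length {len(chain)}", chain)
        masked = np.where(eligible, norms, -1.0)
        chain.append(int(np.argmax(masked)))  # argmax -> smallest tied index
    return chain


def spa_select(X: np.ndarray, y, cfg: SPAConfig | None = None) -> SelectionResult:
    """Exhaustive SPA search over every start column and chain size.

    For each start column a maximal chain is grown once; each prefix of size
    1..max_vars is scored by LOO-LDA cost.  The minimum-cost subset wins,
    ties broken by (smaller size, then smaller start index).
    """
    cfg = cfg or SPAConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    max_m = min(cfg.max_vars, n - 2, p)
    if max_m < 1:
        raise ValueError("training partition too small for any subset size")
    cost_of = _CostCache(X, y)
    best: tuple[float, int, int, list[int]] | None = None  # cost, m, start, subset
    trace: list[float] = []
    for start in range(p):
        try:
            chain = spa_chain(X, start, max_m)
        except RankError as err:
            chain = err.chain
        if not chain:
            continue
        for m in range(1, len(chain) + 1):
            subset = chain[:m]
            c = cost_of(subset)
            cand = (c, m, start, subset)
            if best is None or (c, m, start) < (best[0], best[1], best[2]):
                best = cand
            trace.append(best[0])
    if best is None:
        raise np.linalg.LinAlgError("no evaluable SPA subset")
    cost, m, start, subset = best
    return SelectionResult(
        selected_indices=sorted(subset),
        cost=cost,
        trace=trace,
        method="SPA",
        extras={"start": start, "size": m},
    )


# -- GA --------------------------------------------------------------------


def _tournament(rng, fitness: np.ndarray) -> int:
    i, j = rng.integers(0, len(fitness), size=2)
    if fitness[i] == fitness[j]:
        return int(min(i, j))
    return int(i if fitness[i] > fitness[j] else j)


def _crossover(rng, a: list[int], b: list[int], max_vars: int) -> tuple[list[int], list[int]]:
    # uniform index exchange, then de-duplicate preserving order and truncate
    pool_a, pool_b = [], []
    for g in a:
        (pool_a if rng.random() < 0.5 else pool_b).append(g)
    for g in b:
        (pool_b if rng.random() < 0.5 else pool_a).append(g)

    def dedup(genes: list[int]) -> list[int]:
        seen, out = set(), []
        for g in genes:
            if g not in seen:
                seen.add(g)
                out.append(g)
        return out[:max_vars]

    ca, cb = dedup(pool_a), dedup(pool_b)
    # an empty child inherits one gene from the other parent
    if not ca:
        ca = [a[0]]
    if not cb:
        cb = [b[0]]
    return ca, cb


def _mutate(rng, genes: list[int], p_total: int, rate: float) -> list[int]:
    out = list(genes)
    for pos in range(len(out)):
        if rng.random() < rate:
            unused = [g for g in range(p_total) if g not in out]
            if unused:
                out[pos] = int(rng.choice(unused))
    return out


def ga_select(X: np.ndarray, y, cfg: GAConfig | None = None) -> SelectionResult:
    """Seeded genetic-algorithm search over variable subsets of size <= max_vars.

    Chromosome = list of distinct column indices; fitness = 1 - LOO-LDA
    misclassification on the training partition; tournament selection of
    size 2; crossover (uniform exchange, de-dup, truncate) with the
    configured probability; per-gene mutation to a random unused index;
    single-chromosome elitism.  The best-ever chromosome is returned and the
    per-generation best fitness trace is non-decreasing.
    """
    cfg = cfg or GAConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    max_vars = min(cfg.max_vars, n - 2, p)
    if max_vars < 1:
        raise ValueError("training partition too small for any subset size")
    rng = np.random.default_rng(cfg.seed)
    cost_of = _CostCache(X, y)

    def fitness(genes: list[int]) -> float:
        return 1.0 - cost_of(genes)

    pop = []
    for _ in range(cfg.population):
        size = int(rng.integers(1, max_vars + 1))
        pop.append(list(rng.choice(p, size=size, replace=False).astype(int)))
    fit = np.array([fitness(g) for g in pop])

    def best_of(pop, fit):
        # ties toward fewer variables, then lexicographically smaller genes
        order = sorted(
            range(len(pop)), key=lambda i: (-fit[i], len(pop[i]), sorted(pop[i]))
        )
        return order[0]

    b = best_of(pop, fit)
    best_genes, best_fit = sorted(pop[b]), float(fit[b])
    trace = [best_fit]

    for _ in range(cfg.generations):
        children: list[list[int]] = []
        if cfg.elitism:
            children.append(list(best_genes))
        while len(children) < cfg.population:
            pa = pop[_tournament(rng, fit)]
            pb = pop[_tournament(rng, fit)]
            if rng.random() < cfg.crossover_rate:
                ca, cb = _crossover(rng, pa, pb, max_vars)
            else:
                ca, cb = list(pa), list(pb)
            ca = _mutate(rng, ca, p, cfg.mutation_rate)
            cb = _mutate(rng, cb, p, cfg.mutation_rate)
            children.append(ca)
            if len(children) < cfg.population:
                children.append(cb)
        pop = children
        fit = np.array([fitness(g) for g in pop])
        b = best_of(pop, fit)
        if (fit[b], -len(pop[b])) > (best_fit, -len(best_genes)):
            best_genes, best_fit = sorted(pop[b]), float(fit[b])
        trace.append(best_fit)

    return SelectionResult(
        selected_indices=sorted(best_genes),
        cost=1.0 - best_fit,
        trace=trace,
        method="GA",
        extras={"population": cfg.population, "generations": cfg.generations,
                "seed": cfg.seed},
    )


# -- Fisher weights --------------------------------------------------------


def fisher_weights(X: np.ndarray, y, indices) -> list[dict]:
    """Univariate Fisher discriminant weight and class attribution per index.

    weight_j = (mean_A_j - mean_B_j)^2 / (var_A_j + var_B_j), unbiased
    variances.  Zero pooled variance with distinct means is reported as an
    infinite weight (flag, not an exception).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray([str(c) for c in y])
    labels = sorted(set(y.tolist()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 classes, found {labels}")
    a, b = labels
    Xa, Xb = X[y == a], X[y == b]
    if len(Xa) < 2 or len(Xb) < 2:
        raise ValueError("need at least 2 samples per class")
    out = []
    for j in (int(i) for i in indices):
        ma, mb = Xa[:, j].mean(), Xb[:, j].mean()
        va, vb = Xa[:, j].var(ddof=1), Xb[:, j].var(ddof=1)
        denom = va + vb
        if denom == 0.0:
            weight = float("inf") if ma != mb else 0.0
            infinite = ma != mb
        else:
            weight = (ma - mb) ** 2 / denom
            infinite = False
        out.append(
            {
                "index": j,
                "weight": float(weight),
                "attributed_class": a if ma >= mb else b,
                "infinite": infinite,
            }
        )
    return out
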