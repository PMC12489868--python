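"""Multi-objective cuckoo search over the CLAHE parameter space.

Candidate parameter vectors ("eggs") are perturbed by heavy-tailed Lévy
flights toward members of the current non-dominated archive (exploitation)
and randomly abandoned with probability ``p_discovery`` (exploration, the
host bird discovering the intruder egg).  Selection uses Pareto dominance:
non-dominated sorting ranks the merged population, crowding distance
preserves spread when truncating, and the final parameter set is the middle
of the front — the balanced trade-off between contrast gain and noise
amplification.

Tile counts are searched as continuous values and rounded only when a
vector is decoded for evaluation, so the random walk stays continuous.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .clahe import ClaheParams
from .imaging import GrayImage
from .objectives import FitnessPair, GlcmConfig, evaluate_candidate

__all__ = [
    "SearchBounds",
    "MocsConfig",
    "Candidate",
    "ParetoFront",
    "levy_step",
    "propose_cuckoo",
    "abandon_walk",
    "dominates",
    "nondominated_sort",
    "crowding_distance",
    "select_middle",
    "decode",
    "optimize_objective",
    "optimize",
]

logger = logging.getLogger(__name__)

ObjectiveFn = Callable[[np.ndarray], tuple[float, float]]


@dataclass(frozen=True)
class SearchBounds:
    """Box bounds of the decision space.

    Defaults cover the CLAHE vector (tiles_x, tiles_y, clip_limit, alpha):
    4-12 tiles per axis, clip limit 0.001-0.01, alpha 0.5-0.9.
    """

    lower: np.ndarray = field(
        default_factory=lambda: np.array([4.0, 4.0, 0.001, 0.5])
    )
    upper: np.ndarray = field(
        default_factory=lambda: np.array([12.0, 12.0, 0.01, 0.9])
    )

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=np.float64)
        hi = np.asarray(self.upper, dtype=np.float64)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not np.all(lo < hi):
            raise ValueError("lower bounds must be strictly below upper bounds")
        lo.setflags(write=False)
        hi.setflags(write=False)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class MocsConfig:
    """Optimizer settings.

    ``p_discovery`` is the nest-abandonment probability P_a; the default
    0.75 corresponds to a 25% survival probability.  ``levy_beta`` and
    ``step_scale`` (fraction of each dimension's bound range) are the
    customary cuckoo-search settings.
    """

    population: int = 50
    iterations: int = 20
    p_discovery: float = 0.75
    levy_beta: float = 1.5
    step_scale: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError(f"population must be >= 4, got {self.population}")
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        if not 0.0 <= self.p_discovery <= 1.0:
            raise ValueError(f"p_discovery must be in [0, 1], got {self.p_discovery}")
        if not 1.0 < self.levy_beta <= 2.0:
            raise ValueError(f"levy_beta must be in (1, 2], got {self.levy_beta}")


@dataclass(frozen=True)
class Candidate:
    """A decision vector together with its (natural-sign) fitness."""

    vector: np.ndarray
    fitness: FitnessPair | None = None


@dataclass(frozen=True)
class ParetoFront:
    """Mutually non-dominated candidates with their crowding distances."""

    members: tuple[Candidate, ...]
    crowding: np.ndarray

    @classmethod
    def from_candidates(cls, members: Sequence[Candidate]) -> "ParetoFront":
        members = tuple(members)
        fits = [m.fitness.minimized for m in members]
        for a in fits:
            for b in fits:
                if dominates(a, b):
                    raise ValueError("front members must be mutually non-dominated")
        return cls(members=members, crowding=crowding_distance(fits))

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# dominance machinery


def _as_min(f) -> tuple[float, float]:
    """Coerce a FitnessPair or 2-sequence to the minimization convention."""
    if isinstance(f, FitnessPair):
        t = f.minimized
    else:
        t = (float(f[0]), float(f[1]))
    # non-finite candidates are dominated by everything
    if not (math.isfinite(t[0]) and math.isfinite(t[1])):
        return (math.inf, math.inf)
    return t


def dominates(a, b) -> bool:
    """True iff ``a`` is no worse in both minimized objectives and strictly
    better in at least one."""
    am, bm = _as_min(a), _as_min(b)
    return am[0] <= bm[0] and am[1] <= bm[1] and (am[0] < bm[0] or am[1] < bm[1])


def nondominated_sort(points: Sequence) -> list[list[int]]:
    """Partition indices into Pareto fronts (front 0 dominated by nobody)."""
    pts = [_as_min(p) for p in points]
    n = len(pts)
    if n == 0:
        raise ValueError("cannot sort an empty set of points")
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(pts[i], pts[j]):
                dominated_by[i].append(j)
                n_dominating[j] += 1
            elif dominates(pts[j], pts[i]):
                dominated_by[j].append(i)
                n_dominating[i] += 1
    fronts = [[i for i in range(n) if n_dominating[i] == 0]]
    while True:
        nxt: list[int] = []
        for i in fronts[-1]:
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        if not nxt:
            break
        fronts.append(sorted(nxt))
    return fronts


def crowding_distance(front: Sequence) -> np.ndarray:
    """Per-member crowding distance; boundary members get +infinity.

    For each objective the members are sorted, extremes are marked infinite,
    and interior members accumulate the gap between their neighbours
    normalized by the objective's span; distances sum over objectives.
    """
    pts = np.array([_as_min(p) for p in front], dtype=np.float64)
    n = pts.shape[0]
    if n == 0:
        raise ValueError("crowding distance of an empty front")
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for m in range(pts.shape[1]):
        order = np.argsort(pts[:, m], kind="stable")
        vals = pts[order, m]
        dist[order[0]] = dist[order[-1]] = np.inf
        with np.errstate(invalid="ignore"):
            span = vals[-1] - vals[0]
            if not span > 0:
                continue
            gaps = (vals[2:] - vals[:-2]) / span
        dist[order[1:-1]] += np.nan_to_num(gaps, nan=0.0)
    return dist


def select_middle(front: ParetoFront) -> Candidate:
    """The balanced trade-off: the median-by-contrast member of the front.

    Members are ordered by the contrast objective; ties are broken by larger
    crowding distance, then by lower noise; index floor((n-1)/2) is returned.
    """
    n = len(front)
    if n == 0:
        raise ValueError("cannot select from an empty front")
    keys = [
        (m.fitness.contrast, -front.crowding[k], m.fitness.noise)
        for k, m in enumerate(front.members)
    ]
    order = sorted(range(n), key=lambda k: keys[k])
    return front.members[order[(n - 1) // 2]]


# ---------------------------------------------------------------------------
# random walks


def levy_step(dim: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed Lévy step by the Mantegna algorithm: u / |v|^(1/beta)."""
    if not 1.0 < beta <= 2.0:
        raise ValueError(f"beta must be in (1, 2], got {beta}")
    sigma_u = (
        math.gamma(1.0 + beta)
        * math.sin(math.pi * beta / 2.0)
        / (math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0))
    ) ** (1.0 / beta)
    u = rng.normal(0.0, sigma_u, dim)
    v = rng.normal(0.0, 1.0, dim)
    return u / np.abs(v) ** (1.0 / beta)


def propose_cuckoo(
    x: np.ndarray,
    guide: np.ndarray,
    bounds: SearchBounds,
    cfg: MocsConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Lévy-flight move of ``x`` relative to a front ``guide``, clamped to bounds."""
    step = (
        cfg.step_scale
        * bounds.range
        * levy_step(bounds.dim, cfg.levy_beta, rng)
        * (x - guide)
    )
    return bounds.clip(x + step)


def abandon_walk(
    population: np.ndarray,
    bounds: SearchBounds,
    cfg: MocsConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Biased random walk replacing discovered nests.

    Each coordinate of each nest is, with probability ``p_discovery``,
    replaced by x + r (x_p - x_q) with r ~ U(0, 1) and p, q distinct random
    nests; results are clamped to bounds.
    """
    pop = np.asarray(population, dtype=np.float64)
    n = pop.shape[0]
    if n < 3:
        raise ValueError(f"abandonment walk needs >= 3 nests, got {n}")
    mask = rng.random(pop.shape) < cfg.p_discovery
    p = rng.integers(0, n, size=n)
    q = rng.integers(0, n, size=n)
    clash = p == q
    while np.any(clash):
        q[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = p == q
    r = rng.random((n, 1))
    moved = pop + r * (pop[p] - pop[q])
    return bounds.clip(np.where(mask, moved, pop))


# ---------------------------------------------------------------------------
# main loop


class _Archive:
    """External elitist archive of non-dominated (vector, fitness) pairs."""

    def __init__(self, cap: int) -> None:
        self.cap = cap
        self.vectors: list[np.ndarray] = []
        self.fits: list[tuple[float, float]] = []

    def update(self, vec: np.ndarray, fit: tuple[float, float]) -> None:
        if not (math.isfinite(fit[0]) and math.isfinite(fit[1])):
            return
        for f in self.fits:
            if dominates(f, fit) or f == fit:
                return
        keep = [k for k, f in enumerate(self.fits) if not dominates(fit, f)]
        self.vectors = [self.vectors[k] for k in keep]
        self.fits = [self.fits[k] for k in keep]
        self.vectors.append(vec.copy())
        self.fits.append(fit)
        while len(self.fits) > self.cap:
            cd = crowding_distance(self.fits)
            drop = int(np.argmin(cd))
            del self.vectors[drop]
            del self.fits[drop]

    def sample_guide(self, rng: np.random.Generator) -> np.ndarray:
        """Crowding-weighted draw of a guide vector from the archive."""
        cd = crowding_distance(self.fits)
        finite = cd[np.isfinite(cd)]
        ceil = 2.0 * finite.max() if finite.size and finite.max() > 0 else 1.0
        w = np.where(np.isfinite(cd), cd, ceil) + 1e-12
        return self.vectors[rng.choice(len(self.fits), p=w / w.sum())]

    def snapshot(self) -> list[tuple[float, float]]:
        return list(self.fits)


def _truncate(
    vectors: list[np.ndarray], fits: list[tuple[float, float]], n: int
) -> tuple[list[np.ndarray], list[tuple[float, float]]]:
    """NSGA-style truncation to n: fill whole fronts, split the last by crowding."""
    fronts = nondominated_sort(fits)
    chosen: list[int] = []
    for fr in fronts:
        if len(chosen) + len(fr) <= n:
            chosen.extend(fr)
        else:
            cd = crowding_distance([fits[i] for i in fr])
            order = sorted(range(len(fr)), key=lambda k: -cd[k])
            chosen.extend(fr[k] for k in order[: n - len(chosen)])
            break
    return [vectors[i] for i in chosen], [fits[i] for i in chosen]


def optimize_objective(
    fn: ObjectiveFn, bounds: SearchBounds, cfg: MocsConfig
) -> tuple[list[np.ndarray], list[tuple[float, float]], list[list[tuple[float, float]]]]:
    """Run the cuckoo search on an arbitrary bi-objective function.

    ``fn`` maps a decision vector to two values, both minimized.  Returns
    the archived non-dominated vectors, their objective values, and one
    archive snapshot per iteration.  Fully deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.population

    def safe_eval(x: np.ndarray) -> tuple[float, float]:
        try:
            f = fn(x)
            f = (float(f[0]), float(f[1]))
        except Exception as exc:  # noqa: BLE001 - candidate rejected, not fatal
            logger.warning("evaluation failed at %s: %s", x, exc)
            return (math.inf, math.inf)
        if not (math.isfinite(f[0]) and math.isfinite(f[1])):
            logger.warning("non-finite fitness at %s: %s", x, f)
            return (math.inf, math.inf)
        return f

    X = [bounds.lower + rng.random(bounds.dim) * bounds.range for _ in range(n)]
    F = [safe_eval(x) for x in X]
    archive = _Archive(cap=n)
    for x, f in zip(X, F):
        archive.update(x, f)

    history: list[list[tuple[float, float]]] = []
    for _ in range(cfg.iterations):
        # exploitation: one cuckoo egg per nest, laid in a random nest
        for i in range(n):
            guide = archive.sample_guide(rng)
            x_new = propose_cuckoo(X[i], guide, bounds, cfg, rng)
            f_new = safe_eval(x_new)
            archive.update(x_new, f_new)
            j = int(rng.integers(0, n))
            if dominates(f_new, F[j]):
                X[j], F[j] = x_new, f_new
            elif not dominates(F[j], f_new) and rng.random() < 0.5:
                X[j], F[j] = x_new, f_new

        # exploration: abandonment walk, then elitist merge-and-truncate
        X2 = abandon_walk(np.array(X), bounds, cfg, rng)
        F2 = [safe_eval(x) for x in X2]
        for x, f in zip(X2, F2):
            archive.update(x, f)
        X, F = _truncate(list(X) + list(X2), F + F2, n)
        history.append(archive.snapshot())

    return archive.vectors, archive.fits, history


# ---------------------------------------------------------------------------
# CLAHE-specific wrapper


def decode(vector: np.ndarray, bounds: SearchBounds | None = None) -> ClaheParams:
    """Decode a continuous 4-vector into CLAHE parameters (tiles rounded)."""
    if bounds is None:
        bounds = SearchBounds()
    v = np.asarray(vector, dtype=np.float64)
    if v.shape != (4,):
        raise ValueError(f"expected a 4-vector, got shape {v.shape}")
    if np.any(v < bounds.lower - 1e-9) or np.any(v > bounds.upper + 1e-9):
        raise ValueError(f"vector {v} lies outside bounds")
    tx = int(np.clip(round(v[0]), math.ceil(bounds.lower[0]), math.floor(bounds.upper[0])))
    ty = int(np.clip(round(v[1]), math.ceil(bounds.lower[1]), math.floor(bounds.upper[1])))
    return ClaheParams(tiles_x=tx, tiles_y=ty, clip_limit=float(v[2]), alpha=float(v[3]))


def optimize(
    img: GrayImage,
    bounds: SearchBounds | None = None,
    cfg: MocsConfig | None = None,
    glcm_cfg: GlcmConfig | None = None,
) -> tuple[ClaheParams, ParetoFront, list[list[tuple[float, float]]]]:
    """Tune CLAHE parameters for one image.

    Returns the middle-of-front parameter set, the full Pareto front of
    (contrast, noise) trade-offs, and per-iteration front snapshots (in the
    minimization convention) for trade-off plots.
    """
    bounds = bounds or SearchBounds()
    cfg = cfg or MocsConfig()
    glcm_cfg = glcm_cfg or GlcmConfig()
    if bounds.dim != 4:
        raise ValueError("CLAHE optimization needs 4-dimensional bounds")

    cache: dict[tuple, tuple[float, float]] = {}

    def fn(vec: np.ndarray) -> tuple[float, float]:
        params = decode(vec, bounds)
        key = (params.tiles_x, params.tiles_y, params.clip_limit, params.alpha)
        if key not in cache:
            fp = evaluate_candidate(img, params, glcm_cfg)
            cache[key] = fp.minimized
        return cache[key]

    vectors, fits, history = optimize_objective(fn, bounds, cfg)
    members = [
        Candidate(vector=v, fitness=FitnessPair(contrast=-f[0], noise=f[1]))
        for v, f in zip(vectors, fits)
    ]
    front = ParetoFront.from_candidates(members)
    best = select_middle(front)
    return decode(best.vector, bounds), front, history
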