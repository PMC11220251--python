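"""Genetic-algorithm selection of the matched-filter binarization threshold.

The matched-filter response is rescaled to [0, 255] and rounded to integers,
which ties the data range to the 8-bit chromosome. A threshold T splits the
pixels into a target class (value > T, the bright candidate lesions) and a
background class (value <= T). Threshold quality is the Otsu-style
between-class criterion

    f(T) = p1 * p2 * (mu1 - mu2)^2

with p1, p2 the class pixel COUNTS and mu1, mu2 their mean gray values; an
empty class scores 0. A small GA — 8-bit chromosomes, population 10,
elitism, roulette selection, single-point crossover, per-bit mutation, with
exploration-heavy rates (pc 0.7, pm 0.4) early and conservative rates (0.3,
0.3) late — maximizes f and the best threshold ever seen binarizes the
response into the coarse candidate mask.

Because the search space is only 256 thresholds, ``exhaustive_best`` (one
histogram pass) is also provided; the GA is retained as the specified
optimizer and is validated against the exhaustive answer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAConfig",
    "GAResult",
    "rescale_u8",
    "fitness",
    "fitness_all",
    "exhaustive_best",
    "evolve",
    "coarse_segment",
]


@dataclass
class GAConfig:
    chromosome_length: int = 8
    population_size: int = 10
    p_crossover_early: float = 0.7
    p_mutation_early: float = 0.4
    p_crossover_late: float = 0.3
    p_mutation_late: float = 0.3
    n_generations: int = 50
    late_stage_start: int = 25
    elitism_count: int = 1
    rng_seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.chromosome_length < 1:
            raise ValueError("chromosome_length must be >= 1")
        probs = (
            self.p_crossover_early,
            self.p_mutation_early,
            self.p_crossover_late,
            self.p_mutation_late,
        )
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.late_stage_start < self.n_generations:
            raise ValueError("late_stage_start must precede n_generations")
        if self.elitism_count < 1 or self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be in [1, population_size)")


@dataclass
class GAResult:
    threshold: int
    fitness: float
    generations: int
    seed: int


def rescale_u8(img: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 255] and round to uint8-valued integers.

    A constant image (no dynamic range) maps to all zeros.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a nonempty 2-D image")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.int64)
    scaled = (img - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(scaled), 0, 255).astype(np.int64)


def fitness(threshold: int, img: np.ndarray) -> float:
    """Between-class criterion p1*p2*(mu1-mu2)^2, computed per pixel.

    ``img`` is quantized to [0, 255] first if it is not already integer
    valued in that range. An empty target or background class yields 0.
    """
    q = np.asarray(img)
    if not np.issubdtype(q.dtype, np.integer):
        q = rescale_u8(q)
    target = q > threshold
    p1 = int(target.sum())
    p2 = q.size - p1
    if p1 == 0 or p2 == 0:
        return 0.0
    mu1 = float(q[target].mean())
    mu2 = float(q[~target].mean())
    return float(p1) * float(p2) * (mu1 - mu2) ** 2


def fitness_all(img: np.ndarray) -> np.ndarray:
    """Fitness at every threshold 0..255 from one 256-bin histogram pass."""
    q = np.asarray(img)
    if not np.issubdtype(q.dtype, np.integer):
        q = rescale_u8(q)
    counts = np.bincount(q.ravel(), minlength=256).astype(float)
    sums = counts * np.arange(256, dtype=float)
    c_below = np.cumsum(counts)          # pixels with value <= T
    s_below = np.cumsum(sums)
    n = c_below[-1]
    total = s_below[-1]
    p2 = c_below
    p1 = n - c_below
    with np.errstate(divide="ignore", invalid="ignore"):
        mu2 = np.where(p2 > 0, s_below / p2, 0.0)
        mu1 = np.where(p1 > 0, (total - s_below) / p1, 0.0)
    f = p1 * p2 * (mu1 - mu2) ** 2
    f[(p1 == 0) | (p2 == 0)] = 0.0
    return f


def exhaustive_best(img: np.ndarray) -> GAResult:
    """Exact maximizer over all 256 thresholds; ties go to the smallest."""
    f = fitness_all(img)
    t = int(np.argmax(f))  # argmax returns the first (smallest) maximizer
    return GAResult(threshold=t, fitness=float(f[t]), generations=0, seed=-1)


def _decode(bits: np.ndarray) -> int:
    return int(bits @ (1 << np.arange(bits.size - 1, -1, -1)))


def evolve(img: np.ndarray, cfg: GAConfig | None = None) -> GAResult:
    """Run the GA and return the best threshold ever observed.

    Fully reproducible for a fixed ``cfg.rng_seed``; ties between equal
    fitness values are broken toward the smaller threshold.
    """
    cfg = cfg or GAConfig()
    cfg.validate()
    f_table = fitness_all(img)
    n_thresh = 1 << cfg.chromosome_length
    if n_thresh > 256:
        raise ValueError("chromosome_length > 8 exceeds the 8-bit response range")
    rng = np.random.default_rng(cfg.rng_seed)

    pop = rng.integers(0, 2, size=(cfg.population_size, cfg.chromosome_length))
    best_t, best_f = -1, -1.0

    for gen in range(cfg.n_generations):
        thresholds = np.array([_decode(ch) for ch in pop])
        fits = f_table[thresholds]

        for t, f in zip(thresholds, fits):
            if f > best_f or (f == best_f and t < best_t):
                best_t, best_f = int(t), float(f)

        late = gen >= cfg.late_stage_start
        pc = cfg.p_crossover_late if late else cfg.p_crossover_early
        pm = cfg.p_mutation_late if late else cfg.p_mutation_early

        # elites: highest fitness, smaller threshold on ties
        order = np.lexsort((thresholds, -fits))
        elites = pop[order[: cfg.elitism_count]].copy()

        total = fits.sum()
        n_children = cfg.population_size - cfg.elitism_count
        if total > 0:
            probs = fits / total
            parents = rng.choice(cfg.population_size, size=2 * n_children, p=probs)
        else:
            parents = rng.choice(cfg.population_size, size=2 * n_children)

        children = []
        for k in range(n_children):
            a = pop[parents[2 * k]].copy()
            b = pop[parents[2 * k + 1]].copy()
            if rng.random() < pc and cfg.chromosome_length > 1:
                point = int(rng.integers(1, cfg.chromosome_length))
                a[point:], b[point:] = b[point:].copy(), a[point:].copy()
            child = a if rng.random() < 0.5 else b
            flips = rng.random(cfg.chromosome_length) < pm
            child[flips] ^= 1
            children.append(child)

        pop = np.vstack([elites] + children) if children else elites

    return GAResult(
        threshold=best_t,
        fitness=best_f,
        generations=cfg.n_generations,
        seed=cfg.rng_seed,
    )


def coarse_segment(
    response: np.ndarray, cfg: GAConfig | None = None, return_details: bool = False
):
    """Binarize the matched-filter response at the GA-selected threshold.

    The response is rescaled/quantized to [0, 255]; the mask keeps pixels
    strictly above the threshold (candidate lesions are bright).
    """
    q = rescale_u8(response)
    result = evolve(q, cfg)
    mask = q > result.threshold
    return (mask, result) if return_details else mask
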