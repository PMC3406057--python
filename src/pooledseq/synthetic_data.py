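"""Synthetic strain panels and pooled read-count simulation.

Generates panels of homozygous (isogenic) strains with a configurable site
frequency spectrum, draws per-strain DNA contribution weights (symmetric
Dirichlet, or exactly equal), and simulates pooled sequencing read counts
with depth variation and optional per-read sequencing error.

All randomness flows through :func:`numpy.random.default_rng`; every public
function accepts either an integer seed or an existing ``Generator`` so a
root seed can be split deterministically across pipeline stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "StrainPanel",
    "PoolDesign",
    "SiteReadCounts",
    "PoissonDepth",
    "EmpiricalDepth",
    "DepthModel",
    "generate_panel",
    "draw_contributions",
    "simulate_pool_reads",
    "sample_depths",
    "expected_inverse_depth",
]

SeedLike = Union[int, np.integer, np.random.Generator, np.random.SeedSequence, None]


def as_rng(seed: SeedLike) -> np.random.Generator:
    """Coerce an int seed / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def split_seeds(seed: SeedLike, n: int) -> list[np.random.Generator]:
    """Deterministically split one seed into ``n`` independent generators."""
    if isinstance(seed, np.random.Generator):
        ss = seed.bit_generator.seed_seq  # type: ignore[attr-defined]
    elif isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


# ---------------------------------------------------------------------------
# depth models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoissonDepth:
    """Poisson read-depth model with mean ``mean`` reads per site."""

    mean: float

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValueError(f"Poisson depth mean must be > 0, got {self.mean}")


@dataclass(frozen=True)
class EmpiricalDepth:
    """Empirical depth histogram mapping integer depth -> probability mass."""

    histogram: Mapping[int, float]

    def __post_init__(self) -> None:
        if not self.histogram:
            raise ValueError("empirical depth histogram is empty")
        for d, w in self.histogram.items():
            if int(d) != d or d < 0:
                raise ValueError(f"depth {d!r} is not a non-negative integer")
            if w < 0:
                raise ValueError(f"negative histogram mass at depth {d}")
        if not math.isclose(sum(self.histogram.values()), 1.0, abs_tol=1e-6):
            raise ValueError("empirical depth histogram must sum to 1")


DepthModel = Union[PoissonDepth, EmpiricalDepth]


def sample_depths(
    model: DepthModel, n: int, min_depth: int = 0, seed: SeedLike = None
) -> np.ndarray:
    """Draw ``n`` integer depths, conditioned on ``depth >= min_depth``.

    Conditioning truncates and renormalises the model — it never clips draws
    upward, so the returned distribution is the model restricted to the
    retained support.

    Parameters
    ----------
    model
        A :class:`PoissonDepth` or :class:`EmpiricalDepth`.
    n
        Number of depths to draw (>= 1).
    min_depth
        Lower conditioning bound; 0 disables conditioning.
    seed
        Integer seed or ``numpy`` Generator.

    Raises
    ------
    ValueError
        If conditioning is impossible (no model mass at or above
        ``min_depth``) or ``n < 1``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = as_rng(seed)
    if isinstance(model, PoissonDepth):
        if min_depth > 0:
            tail = stats.poisson.sf(min_depth - 1, model.mean)
            if tail < 1e-12:
                raise ValueError(
                    f"Poisson(mean={model.mean}) has essentially no mass at "
                    f"depth >= {min_depth}; conditioning impossible"
                )
            out = np.empty(n, dtype=np.int64)
            filled = 0
            while filled < n:
                need = n - filled
                # oversample to cover expected rejections in one pass
                batch = rng.poisson(model.mean, size=max(int(need / tail * 1.1) + 16, need))
                keep = batch[batch >= min_depth][:need]
                out[filled : filled + keep.size] = keep
                filled += keep.size
            return out
        return rng.poisson(model.mean, size=n).astype(np.int64)
    if isinstance(model, EmpiricalDepth):
        depths = np.array(sorted(model.histogram), dtype=np.int64)
        probs = np.array([model.histogram[int(d)] for d in depths], dtype=float)
        if min_depth > 0:
            keep = depths >= min_depth
            depths, probs = depths[keep], probs[keep]
            if depths.size == 0 or probs.sum() <= 0:
                raise ValueError(
                    f"empirical histogram has no mass at depth >= {min_depth}"
                )
        probs = probs / probs.sum()
        return rng.choice(depths, size=n, p=probs)
    raise TypeError(f"unknown depth model: {model!r}")


def expected_inverse_depth(model: DepthModel, min_depth: int = 0) -> float:
    """E[1/d] under the (conditioned) depth model, by direct summation.

    Used as the analytic oracle for the composite sampling variance
    q(1-q)*E[1/d] of pooled frequency estimates.
    """
    if isinstance(model, PoissonDepth):
        lo = max(min_depth, 1)
        hi = int(model.mean + 20 * math.sqrt(model.mean) + 50)
        d = np.arange(lo, hi + 1)
        pmf = stats.poisson.pmf(d, model.mean)
        mass = pmf.sum()
        if mass < 1e-12:
            raise ValueError("no usable mass in conditioned Poisson model")
        return float((pmf / mass) @ (1.0 / d))
    if isinstance(model, EmpiricalDepth):
        items = [(d, w) for d, w in model.histogram.items() if d >= max(min_depth, 1)]
        mass = sum(w for _, w in items)
        if mass <= 0:
            raise ValueError("no usable mass in conditioned empirical model")
        return sum(w / d for d, w in items) / mass
    raise TypeError(f"unknown depth model: {model!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class StrainPanel:
    """Binary genotype matrix for a panel of homozygous strains.

    Attributes
    ----------
    genotypes
        ``(n_strains, n_sites)`` matrix of {0, 1}; 1 marks the non-reference
        allele. Strains are isogenic, so there are no heterozygotes.
    site_ids
        Ordered per-site labels.
    truth_freq
        Per-site "true" allele frequency: either the source-population
        frequency the column was drawn from, or the realised column mean
        when the panel itself defines truth.
    strain_ids
        Ordered per-strain labels.
    """

    genotypes: np.ndarray
    site_ids: np.ndarray
    truth_freq: np.ndarray
    strain_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (strains x sites)")
        if not np.isin(self.genotypes, (0, 1)).all():
            raise ValueError("genotypes must contain only 0/1 (isogenic strains)")
        self.genotypes = self.genotypes.astype(np.int8)
        self.site_ids = np.asarray(self.site_ids)
        self.truth_freq = np.asarray(self.truth_freq, dtype=float)
        if self.site_ids.shape[0] != self.n_sites or self.truth_freq.shape[0] != self.n_sites:
            raise ValueError("site_ids/truth_freq length must match n_sites")
        if ((self.truth_freq < 0) | (self.truth_freq > 1)).any():
            raise ValueError("truth_freq must lie in [0, 1]")
        if self.strain_ids is None:
            self.strain_ids = np.array([f"strain_{i + 1}" for i in range(self.n_strains)])
        else:
            self.strain_ids = np.asarray(self.strain_ids)
            if self.strain_ids.shape[0] != self.n_strains:
                raise ValueError("strain_ids length must match n_strains")

    @property
    def n_strains(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def panel_freq(self) -> np.ndarray:
        """Realised per-site allele frequency among the pooled strains."""
        return self.genotypes.mean(axis=0)

    def subset_strains(self, index: Sequence[int]) -> "StrainPanel":
        """Panel restricted to the given strain rows; truth_freq is kept
        (source-population truth does not change when fewer strains are pooled)."""
        index = np.asarray(index)
        return StrainPanel(
            genotypes=self.genotypes[index],
            site_ids=self.site_ids,
            truth_freq=self.truth_freq,
            strain_ids=self.strain_ids[index],
        )


@dataclass(frozen=True)
class PoolDesign:
    """Library-level design of one pooled sequencing experiment.

    ``weights`` is the per-strain DNA share on the simplex; ``depth_model``
    generates per-site total depth (conditioned on ``min_depth`` so every
    simulated site survives the analysis filter); ``error_rate`` is the
    per-read allele-flip probability.
    """

    weights: np.ndarray
    depth_model: DepthModel
    error_rate: float = 0.0
    min_depth: int = 10

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if (w < 0).any():
            raise ValueError("contribution weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"contribution weights must sum to 1 (got {w.sum()!r})")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError(f"error_rate must be in [0, 0.5), got {self.error_rate}")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class SiteReadCounts:
    """Per-site (non-reference count, total depth) for one pooled library."""

    site_ids: np.ndarray
    nonref: np.ndarray
    depth: np.ndarray
    library_id: str = "pool"

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids)
        self.nonref = np.asarray(self.nonref, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if not (self.site_ids.shape == self.nonref.shape == self.depth.shape):
            raise ValueError("site_ids, nonref and depth must have equal length")
        if (self.nonref < 0).any() or (self.depth < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.nonref > self.depth).any():
            bad = self.site_ids[self.nonref > self.depth][:5]
            raise ValueError(f"nonref > depth at sites {list(bad)}")

    @property
    def n_sites(self) -> int:
        return self.site_ids.shape[0]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

_NEUTRAL_GRID = 200  # grid resolution for the 1/x spectrum


def _draw_site_frequencies(
    sfs: Union[str, Sequence[float]], n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    if isinstance(sfs, str):
        kind = sfs.lower()
        if kind == "uniform":
            return rng.uniform(0.0, 1.0, size=n_sites)
        if kind == "neutral":
            # density proportional to 1/x on a bounded grid of frequencies
            k = np.arange(1, _NEUTRAL_GRID)
            p = (1.0 / k) / (1.0 / k).sum()
            return rng.choice(k / _NEUTRAL_GRID, size=n_sites, p=p)
        raise ValueError(f"unknown sfs spec {sfs!r}; use 'uniform', 'neutral' or a list")
    freqs = np.asarray(list(sfs), dtype=float)
    if freqs.size == 0:
        raise ValueError("fixed-list sfs must be non-empty")
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("fixed-list frequencies must lie in [0, 1]")
    if freqs.size == n_sites:
        return freqs  # positional: caller pinned each site's frequency
    return rng.choice(freqs, size=n_sites)


def generate_panel(
    n_strains: int,
    n_sites: int,
    sfs: Union[str, Sequence[float]] = "uniform",
    seed: SeedLike = None,
    truth: str = "population",
) -> StrainPanel:
    """Generate a panel of isogenic strains from a site frequency spectrum.

    Each site independently draws a population frequency ``p_j`` from ``sfs``
    ('uniform', 'neutral', or an explicit list of frequencies — a list whose
    length equals ``n_sites`` is used positionally), then each strain carries
    the non-reference allele with probability ``p_j``.

    ``truth='population'`` stores ``p_j`` as the truth frequency (the panel is
    a sample from a larger source population); ``truth='panel'`` stores the
    realised column mean.
    """
    if n_strains < 2:
        raise ValueError(f"n_strains must be >= 2, got {n_strains}")
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    if truth not in ("population", "panel"):
        raise ValueError(f"truth must be 'population' or 'panel', got {truth!r}")
    rng = as_rng(seed)
    p = _draw_site_frequencies(sfs, n_sites, rng)
    genotypes = (rng.random((n_strains, n_sites)) < p).astype(np.int8)
    truth_freq = p if truth == "population" else genotypes.mean(axis=0)
    site_ids = np.array([f"site_{j + 1}" for j in range(n_sites)])
    return StrainPanel(genotypes=genotypes, site_ids=site_ids, truth_freq=truth_freq)


def draw_contributions(
    n_strains: int, concentration: float = 20.0, seed: SeedLike = None
) -> np.ndarray:
    """Draw per-strain DNA contribution weights.

    Finite ``concentration`` draws once from a symmetric
    Dirichlet(concentration); ``math.inf`` returns exactly equal weights
    (the ideal pool). The default of 20 produces a visible gradation in
    per-strain representation without extreme outliers.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if not concentration > 0:
        raise ValueError(f"concentration must be > 0, got {concentration}")
    if math.isinf(concentration):
        return np.full(n_strains, 1.0 / n_strains)
    rng = as_rng(seed)
    return rng.dirichlet(np.full(n_strains, float(concentration)))


def simulate_pool_reads(
    panel: StrainPanel, design: PoolDesign, seed: SeedLike = None, library_id: str = "pool"
) -> SiteReadCounts:
    """Simulate pooled read counts for every site of a panel.

    Per site ``j`` the pooled non-reference DNA fraction is
    ``q_j = sum_i w_i * g_ij``; depth ``d_j`` comes from the design's depth
    model conditioned on ``min_depth``; the non-reference read count is
    ``Binomial(d_j, q_j (1 - eps) + (1 - q_j) eps)``. This is exactly the
    per-read composite of strain picking followed by error flipping.
    """
    w = design.weights
    if w.shape[0] != panel.n_strains:
        raise ValueError(
            f"design has {w.shape[0]} weights but panel has {panel.n_strains} strains"
        )
    rng_depth, rng_reads = split_seeds(seed, 2)
    q = np.clip(w @ panel.genotypes, 0.0, 1.0)  # guard float dust on the simplex
    eps = design.error_rate
    prob = q * (1.0 - eps) + (1.0 - q) * eps
    depth = sample_depths(design.depth_model, panel.n_sites, design.min_depth, rng_depth)
    nonref = rng_reads.binomial(depth, prob)
    return SiteReadCounts(
        site_ids=panel.site_ids, nonref=nonref, depth=depth, library_id=library_id
    )
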