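"""Accuracy machinery for pooled allele-frequency estimates.

Implements Lin's concordance correlation coefficient, the squared relative
error statistic, frequency-binned resampling (20 bins of 5%, 50 sites per
bin, 1000 sites per replicate, 100 replicates by default), and the binomial
expectation simulation that gives the best-case accuracy attainable when the
only noise is read sampling at the observed depths.

Two comparison modes are supported: an estimate against truth frequencies,
and two replicate libraries against each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from pooledseq.pool_freq import FrequencyTable
from pooledseq.synthetic_data import (
    PoissonDepth,
    SeedLike,
    as_rng,
    sample_depths,
    split_seeds,
)

__all__ = [
    "ResampleDesign",
    "AccuracyReport",
    "lin_ccc",
    "relative_error",
    "binned_resample",
    "binomial_expectation",
    "accuracy_experiment",
    "binomial_ccc_benchmark",
    "write_accuracy_report",
]

logger = logging.getLogger(__name__)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean(x) - mean(y))^2)

    with population (1/n) moment denominators. Equals 1 only for exact
    agreement with the identity line; penalises location and scale shifts
    as well as dispersion.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 2 points, or two constant vectors
        (the coefficient is undefined: zero over zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D vectors, got {x.shape} vs {y.shape}")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("both vectors are constant and equal; concordance undefined")
    return float(np.clip(2.0 * sxy / denom, -1.0, 1.0))


def relative_error(est, truth, site_ids=None) -> tuple[np.ndarray, float]:
    """Per-site squared relative error ((est - truth) / truth)^2 and its mean.

    Truth values must be strictly positive; a zero denominator raises with
    the offending site named (callers exclude monomorphic-reference sites
    upstream).
    """
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError("est and truth must have equal length")
    zero = truth == 0.0
    if zero.any():
        if site_ids is not None:
            names = list(np.asarray(site_ids)[zero][:5])
        else:
            names = list(np.flatnonzero(zero)[:5])
        raise ValueError(
            f"relative error undefined at truth frequency 0 (sites {names}); "
            "exclude such sites before calling"
        )
    per_site = ((est - truth) / truth) ** 2
    return per_site, float(per_site.mean())


@dataclass(frozen=True)
class ResampleDesign:
    """Frequency-binned resampling design: n_bins of bin_width, per_bin each."""

    n_bins: int = 20
    bin_width: float = 0.05
    per_bin: int = 50

    def __post_init__(self) -> None:
        if abs(self.n_bins * self.bin_width - 1.0) > 1e-12:
            raise ValueError("n_bins * bin_width must equal 1")
        if self.per_bin < 1:
            raise ValueError("per_bin must be >= 1")

    @property
    def sites_per_rep(self) -> int:
        return self.n_bins * self.per_bin


def bin_index(freq, design: ResampleDesign) -> np.ndarray:
    """Half-open bin assignment [k*w, (k+1)*w); frequency 1.0 joins the last bin."""
    freq = np.asarray(freq, dtype=float)
    idx = np.floor(freq / design.bin_width).astype(np.int64)
    return np.minimum(idx, design.n_bins - 1)


def binned_resample(
    truth,
    design: ResampleDesign = ResampleDesign(),
    seed: SeedLike = None,
    allow_short_bins: bool = False,
) -> np.ndarray:
    """Sample site indices stratified by truth-frequency bin.

    Draws exactly ``per_bin`` distinct indices from every bin, without
    replacement. A bin with fewer sites than ``per_bin`` is an error unless
    ``allow_short_bins`` is set, in which case ``per_bin`` is downscaled to
    the minimum bin occupancy (warned loudly); an empty bin is always fatal.
    """
    rng = as_rng(seed)
    truth = np.asarray(truth, dtype=float)
    bins = bin_index(truth, design)
    members = [np.flatnonzero(bins == k) for k in range(design.n_bins)]
    occupancy = np.array([m.size for m in members])
    if (occupancy == 0).any():
        empty = np.flatnonzero(occupancy == 0)
        raise ValueError(f"frequency bins {list(empty)} contain no sites")
    per_bin = design.per_bin
    if (occupancy < per_bin).any():
        if not allow_short_bins:
            short = np.flatnonzero(occupancy < per_bin)
            raise ValueError(
                f"bins {list(short)} hold fewer than per_bin={per_bin} sites "
                f"(min occupancy {occupancy.min()}); pass allow_short_bins to downscale"
            )
        per_bin = int(occupancy.min())
        logger.warning(
            "short bins: downscaling per_bin from %d to minimum occupancy %d",
            design.per_bin,
            per_bin,
        )
    picks = [rng.choice(m, size=per_bin, replace=False) for m in members]
    return np.concatenate(picks)


def binomial_expectation(truth, depths, seed: SeedLike = None) -> np.ndarray:
    """Simulated frequency estimates under pure binomial read sampling.

    Per site j returns B_j / d_j with B_j ~ Binomial(d_j, truth_j) — read
    sampling only, no strain-contribution layer. This is the accuracy
    expected of an ideal pool at the observed depths.
    """
    truth = np.asarray(truth, dtype=float)
    depths = np.asarray(depths, dtype=np.int64)
    if truth.shape != depths.shape:
        raise ValueError("truth and depths must have equal length")
    if (depths < 1).any():
        raise ValueError("depths must be >= 1")
    rng = as_rng(seed)
    return rng.binomial(depths, truth) / depths


@dataclass
class AccuracyReport:
    """Observed and binomial-expected accuracy over resampling replicates.

    Per-replicate concordance and mean-relative-error values for the observed
    estimates and for fresh binomial simulations at the same sites/depths;
    summarised as (min, max) ranges over replicates.
    """

    mode: str
    n_reps: int
    design: ResampleDesign
    observed_ccc: np.ndarray
    expected_ccc: np.ndarray
    observed_relerr: np.ndarray
    expected_relerr: np.ndarray
    library_id: str = "pool"
    library_id_2: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("observed_ccc", "expected_ccc", "observed_relerr", "expected_relerr"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape[0] != self.n_reps:
                raise ValueError(f"{name} must hold exactly n_reps={self.n_reps} values")
        if ((np.abs(self.observed_ccc) > 1) | (np.abs(self.expected_ccc) > 1)).any():
            raise ValueError("concordance values must lie in [-1, 1]")
        if (self.observed_relerr < 0).any() or (self.expected_relerr < 0).any():
            raise ValueError("relative errors must be >= 0")

    def range(self, which: str) -> tuple[float, float]:
        v = getattr(self, which)
        return float(v.min()), float(v.max())

    def summary(self) -> dict:
        out = {"mode": self.mode, "n_reps": self.n_reps, "library_id": self.library_id}
        if self.library_id_2 is not None:
            out["library_id_2"] = self.library_id_2
        for which in ("observed_ccc", "expected_ccc", "observed_relerr", "expected_relerr"):
            lo, hi = self.range(which)
            out[which] = {
                "min": lo,
                "max": hi,
                "mean": float(getattr(self, which).mean()),
            }
        return out


def _relerr_mask(denom: np.ndarray) -> np.ndarray:
    # boundary frequencies join end bins for concordance but are excluded
    # from the relative-error statistic (zero denominator / degenerate site)
    return (denom > 0.0) & (denom < 1.0)


def accuracy_experiment(
    est_table: FrequencyTable,
    mode: str = "vs_truth",
    design: ResampleDesign = ResampleDesign(),
    n_reps: int = 100,
    seed: SeedLike = None,
    est_table_2: Optional[FrequencyTable] = None,
    allow_short_bins: bool = False,
) -> AccuracyReport:
    """Run the binned-resampling accuracy experiment.

    Per replicate: draw a stratified sample of sites on truth frequencies,
    compute the observed concordance and mean relative error — estimate vs
    truth in ``vs_truth`` mode, estimate vs estimate in ``replicate`` mode —
    then compute the same statistics on fresh binomial draws at the sampled
    sites' observed depths (two independent draws, one per library, in
    replicate mode). Reports per-rep values; ranges summarise them.

    The observed and expected statistics within one replicate share the same
    resampled site set.
    """
    if mode not in ("vs_truth", "replicate"):
        raise ValueError(f"mode must be 'vs_truth' or 'replicate', got {mode!r}")
    if est_table.truth_freq is None:
        raise ValueError("est_table must carry truth_freq")
    if mode == "replicate":
        if est_table_2 is None:
            raise ValueError("replicate mode needs est_table_2")
        if est_table_2.n_sites != est_table.n_sites or not np.array_equal(
            est_table.site_ids, est_table_2.site_ids
        ):
            raise ValueError("replicate tables must share the same site set and order")

    truth = est_table.truth_freq
    rngs = split_seeds(seed, n_reps)
    obs_ccc = np.empty(n_reps)
    exp_ccc = np.empty(n_reps)
    obs_rel = np.empty(n_reps)
    exp_rel = np.empty(n_reps)

    for r, rng in enumerate(rngs):
        idx = binned_resample(truth, design, seed=rng, allow_short_bins=allow_short_bins)
        t = truth[idx]
        d1 = est_table.depth[idx]
        e1 = est_table.est_freq[idx]
        sim1 = binomial_expectation(t, d1, seed=rng)
        if mode == "vs_truth":
            obs_ccc[r] = lin_ccc(e1, t)
            exp_ccc[r] = lin_ccc(sim1, t)
            mask = _relerr_mask(t)
            obs_rel[r] = relative_error(e1[mask], t[mask])[1]
            exp_rel[r] = relative_error(sim1[mask], t[mask])[1]
        else:
            d2 = est_table_2.depth[idx]
            e2 = est_table_2.est_freq[idx]
            sim2 = binomial_expectation(t, d2, seed=rng)
            obs_ccc[r] = lin_ccc(e1, e2)
            exp_ccc[r] = lin_ccc(sim1, sim2)
            mask_obs = _relerr_mask(e2)
            obs_rel[r] = relative_error(e1[mask_obs], e2[mask_obs])[1]
            mask_exp = _relerr_mask(sim2)
            exp_rel[r] = relative_error(sim1[mask_exp], sim2[mask_exp])[1]

    return AccuracyReport(
        mode=mode,
        n_reps=n_reps,
        design=design,
        observed_ccc=obs_ccc,
        expected_ccc=exp_ccc,
        observed_relerr=obs_rel,
        expected_relerr=exp_rel,
        library_id=est_table.library_id,
        library_id_2=None if est_table_2 is None else est_table_2.library_id,
    )


def binomial_ccc_benchmark(
    depth_mean: float,
    mode: str = "vs_truth",
    n_sites: int = 100_000,
    n_reps: int = 100,
    min_depth: int = 10,
    design: ResampleDesign = ResampleDesign(),
    seed: SeedLike = None,
) -> AccuracyReport:
    """Best-case concordance of pure binomial read sampling.

    Generates ``n_sites`` truth frequencies uniform on (0, 1), per-site
    depths from a Poisson of the given mean conditioned on ``min_depth``,
    and one binomial frequency estimate per site, then runs the binned
    resampling experiment. In ``replicate`` mode a second independent
    depth vector and estimate stand in for a replicate library, and the
    expected concordance is that of two independent binomial samples of
    the same truth — the idealised replicate-pool comparison.
    """
    rng_truth, rng_d1, rng_d2, rng_e1, rng_e2, rng_acc = split_seeds(seed, 6)
    truth = rng_truth.uniform(0.0, 1.0, size=n_sites)
    model = PoissonDepth(depth_mean)
    site_ids = np.arange(n_sites)
    d1 = sample_depths(model, n_sites, min_depth, rng_d1)
    t1 = FrequencyTable(
        site_ids=site_ids,
        est_freq=binomial_expectation(truth, d1, rng_e1),
        depth=d1,
        truth_freq=truth,
        library_id=f"binomial_{depth_mean:g}x",
    )
    if mode == "replicate":
        d2 = sample_depths(model, n_sites, min_depth, rng_d2)
        t2 = FrequencyTable(
            site_ids=site_ids,
            est_freq=binomial_expectation(truth, d2, rng_e2),
            depth=d2,
            truth_freq=truth,
            library_id=f"binomial_{depth_mean:g}x_rep2",
        )
        return accuracy_experiment(
            t1, mode="replicate", est_table_2=t2, design=design, n_reps=n_reps, seed=rng_acc
        )
    return accuracy_experiment(t1, mode="vs_truth", design=design, n_reps=n_reps, seed=rng_acc)


def write_accuracy_report(report: AccuracyReport, path) -> None:
    """TSV of per-rep statistics plus a summary row of min-max ranges."""
    with open(path, "w") as fh:
        fh.write(
            "rep\tobserved_ccc\texpected_ccc\tobserved_relerr\texpected_relerr\n"
        )
        for r in range(report.n_reps):
            fh.write(
                f"{r + 1}\t{report.observed_ccc[r]:.6f}\t{report.expected_ccc[r]:.6f}"
                f"\t{report.observed_relerr[r]:.6f}\t{report.expected_relerr[r]:.6f}\n"
            )
        parts = []
        for which in ("observed_ccc", "expected_ccc", "observed_relerr", "expected_relerr"):
            lo, hi = report.range(which)
            parts.append(f"{lo:.3f}-{hi:.3f}")
        fh.write("range\t" + "\t".join(parts) + "\n")
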