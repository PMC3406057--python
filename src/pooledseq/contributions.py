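"""Per-strain DNA contribution estimation from private SNPs.

A SNP private to one strain reaches the pool only through that strain's DNA,
so its pooled frequency estimates the strain's DNA share. Shares are
reported as the mean over resampling replicates (50 private SNPs per strain
per replicate, 10 replicates) with a 2-standard-deviation band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from pooledseq.pool_freq import FrequencyTable
from pooledseq.synthetic_data import SeedLike, SiteReadCounts, StrainPanel, split_seeds

__all__ = [
    "PrivateSnpMap",
    "ContributionReport",
    "find_private_snps",
    "estimate_contributions",
    "write_contribution_report",
]

logger = logging.getLogger(__name__)


@dataclass
class PrivateSnpMap:
    """Per-strain site ids carried by exactly that strain and no other."""

    strain_ids: np.ndarray
    sites_by_strain: dict[str, np.ndarray]
    min_pool_depth: int = 10

    def __post_init__(self) -> None:
        seen: set = set()
        for strain, sites in self.sites_by_strain.items():
            s = set(np.asarray(sites).tolist())
            if seen & s:
                raise ValueError(f"sites {sorted(seen & s)[:5]} listed for multiple strains")
            seen |= s

    def n_private(self, strain: str) -> int:
        return len(self.sites_by_strain.get(strain, ()))


@dataclass
class ContributionReport:
    """Estimated per-strain DNA shares, sorted by mean share.

    ``mean`` is the mean over replicate means; the band is ``mean ± 2 sd``
    with sd the sample standard deviation over replicates.
    """

    strain_ids: np.ndarray
    mean_share: np.ndarray
    sd: np.ndarray
    n_private: np.ndarray
    per_strain: int = 50
    reps: int = 10
    dropped: list = field(default_factory=list)

    @property
    def lo2sd(self) -> np.ndarray:
        return self.mean_share - 2.0 * self.sd

    @property
    def hi2sd(self) -> np.ndarray:
        return self.mean_share + 2.0 * self.sd


def find_private_snps(
    panel: StrainPanel,
    pool_counts: SiteReadCounts,
    min_pool_depth: int = 10,
    per_strain_depth_ok: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> PrivateSnpMap:
    """Identify SNPs carried by exactly one strain with adequate pool depth.

    A site qualifies when its genotype column has exactly one carrier and the
    pooled library covers it to more than ``min_pool_depth`` reads.
    ``per_strain_depth_ok`` is a vectorised predicate over site indices used
    in real-data mode to gate eligibility by per-strain coverage; synthetic
    genotypes are exact, so the default accepts every site.
    """
    if pool_counts.n_sites != panel.n_sites or not np.array_equal(
        panel.site_ids, pool_counts.site_ids
    ):
        raise ValueError("panel and pool counts must share the same site list")
    carriers = panel.genotypes.sum(axis=0)
    eligible = (carriers == 1) & (pool_counts.depth > min_pool_depth)
    if per_strain_depth_ok is not None:
        idx = np.flatnonzero(eligible)
        eligible_idx = idx[np.asarray(per_strain_depth_ok(idx), dtype=bool)]
    else:
        eligible_idx = np.flatnonzero(eligible)
    owner = panel.genotypes[:, eligible_idx].argmax(axis=0)
    sites_by_strain = {
        str(sid): panel.site_ids[eligible_idx[owner == i]]
        for i, sid in enumerate(panel.strain_ids)
    }
    return PrivateSnpMap(
        strain_ids=np.asarray(panel.strain_ids),
        sites_by_strain=sites_by_strain,
        min_pool_depth=min_pool_depth,
    )


def estimate_contributions(
    pmap: PrivateSnpMap,
    freqs: FrequencyTable,
    per_strain: int = 50,
    reps: int = 10,
    seed: SeedLike = None,
) -> ContributionReport:
    """Estimate each strain's DNA share from its private-SNP pool frequencies.

    Per strain and replicate, ``per_strain`` private SNPs are sampled without
    replacement and their mean pooled frequency recorded; the report carries
    the mean and sample SD over replicates. Strains with fewer than
    ``per_strain`` private SNPs retained in ``freqs`` (sites may have been
    depth-filtered away) are dropped with a warning.
    """
    site_pos = {s: i for i, s in enumerate(freqs.site_ids)}
    rngs = split_seeds(seed, len(pmap.strain_ids))
    kept_ids, means, sds, n_priv = [], [], [], []
    dropped = []
    for strain, rng in zip(pmap.strain_ids, rngs):
        sites = np.asarray(pmap.sites_by_strain.get(str(strain), ()))
        rows = np.array([site_pos[s] for s in sites if s in site_pos], dtype=np.int64)
        if rows.size < per_strain:
            dropped.append(str(strain))
            logger.warning(
                "strain %s has only %d private SNPs (< per_strain=%d); dropped",
                strain,
                rows.size,
                per_strain,
            )
            continue
        rep_means = np.array(
            [freqs.est_freq[rng.choice(rows, size=per_strain, replace=False)].mean() for _ in range(reps)]
        )
        kept_ids.append(str(strain))
        means.append(rep_means.mean())
        sds.append(rep_means.std(ddof=1))
        n_priv.append(rows.size)
    order = np.argsort(means)
    return ContributionReport(
        strain_ids=np.asarray(kept_ids)[order],
        mean_share=np.asarray(means)[order],
        sd=np.asarray(sds)[order],
        n_private=np.asarray(n_priv)[order],
        per_strain=per_strain,
        reps=reps,
        dropped=dropped,
    )


def write_contribution_report(report: ContributionReport, path) -> None:
    """TSV: strain_id, n_private, mean_share, sd, lo2sd, hi2sd (sorted by share)."""
    with open(path, "w") as fh:
        fh.write("strain_id\tn_private\tmean_share\tsd\tlo2sd\thi2sd\n")
        for i, strain in enumerate(report.strain_ids):
            fh.write(
                f"{strain}\t{report.n_private[i]}\t{report.mean_share[i]:.6f}"
                f"\t{report.sd[i]:.6f}\t{report.lo2sd[i]:.6f}\t{report.hi2sd[i]:.6f}\n"
            )
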