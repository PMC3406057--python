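"""Pooled allele-frequency estimation from read counts.

Frequencies are the fraction of reads carrying the non-reference allele,
restricted to sites passing a minimum-depth filter (default 10x). Libraries
can be merged at the read-count level, the way physically re-pooled or
co-sequenced libraries combine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from pooledseq.synthetic_data import SiteReadCounts

__all__ = [
    "FrequencyTable",
    "estimate_frequencies",
    "merge_libraries",
    "intersect_on_filter",
    "attach_truth",
]


@dataclass
class FrequencyTable:
    """Per-site pooled allele-frequency estimates for retained sites.

    ``est_freq[j]`` is exactly ``nonref[j] / depth[j]`` and every retained
    site has ``depth >= min_depth``. ``truth_freq`` is optional and carried
    along for accuracy analyses.
    """

    site_ids: np.ndarray
    est_freq: np.ndarray
    depth: np.ndarray
    library_id: str = "pool"
    truth_freq: Optional[np.ndarray] = None
    min_depth: int = 0

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids)
        self.est_freq = np.asarray(self.est_freq, dtype=float)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        n = self.site_ids.shape[0]
        if self.est_freq.shape[0] != n or self.depth.shape[0] != n:
            raise ValueError("site_ids, est_freq and depth must have equal length")
        if ((self.est_freq < 0) | (self.est_freq > 1)).any():
            raise ValueError("est_freq must lie in [0, 1]")
        if self.truth_freq is not None:
            self.truth_freq = np.asarray(self.truth_freq, dtype=float)
            if self.truth_freq.shape[0] != n:
                raise ValueError("truth_freq length must match site_ids")

    @property
    def n_sites(self) -> int:
        return self.site_ids.shape[0]

    def subset(self, mask_or_index) -> "FrequencyTable":
        idx = np.asarray(mask_or_index)
        return FrequencyTable(
            site_ids=self.site_ids[idx],
            est_freq=self.est_freq[idx],
            depth=self.depth[idx],
            library_id=self.library_id,
            truth_freq=None if self.truth_freq is None else self.truth_freq[idx],
            min_depth=self.min_depth,
        )


def estimate_frequencies(
    counts: SiteReadCounts,
    min_depth: int = 10,
    truth_freq: Optional[np.ndarray] = None,
) -> FrequencyTable:
    """Non-reference read fraction at sites covered to at least ``min_depth``.

    Sites below the depth filter are dropped; site order is preserved.
    ``truth_freq``, if given, must align with ``counts.site_ids`` and is
    subset alongside.
    """
    keep = counts.depth >= min_depth
    depth = counts.depth[keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(depth > 0, counts.nonref[keep] / np.maximum(depth, 1), 0.0)
    truth = None
    if truth_freq is not None:
        truth_freq = np.asarray(truth_freq, dtype=float)
        if truth_freq.shape[0] != counts.n_sites:
            raise ValueError("truth_freq length must match counts")
        truth = truth_freq[keep]
    return FrequencyTable(
        site_ids=counts.site_ids[keep],
        est_freq=est,
        depth=depth,
        library_id=counts.library_id,
        truth_freq=truth,
        min_depth=min_depth,
    )


def merge_libraries(
    a: SiteReadCounts, b: SiteReadCounts, library_id: Optional[str] = None
) -> SiteReadCounts:
    """Merge two libraries by summing read counts per site.

    Mimics pooling the raw reads of both libraries: a site absent from one
    library contributes (0, 0) there, so merging never drops sites. The
    merged frequency is the depth-weighted mean of the input frequencies.
    Site order follows ``a``, with ``b``-only sites appended in ``b`` order.
    """
    if library_id is None:
        library_id = f"{a.library_id}+{b.library_id}"
    a_ids = list(a.site_ids)
    a_index = {s: i for i, s in enumerate(a_ids)}
    extra = [s for s in b.site_ids if s not in a_index]
    site_ids = np.array(a_ids + extra)
    nonref = np.zeros(site_ids.shape[0], dtype=np.int64)
    depth = np.zeros(site_ids.shape[0], dtype=np.int64)
    nonref[: a.n_sites] += a.nonref
    depth[: a.n_sites] += a.depth
    pos = {s: i for i, s in enumerate(site_ids)}
    b_pos = np.array([pos[s] for s in b.site_ids], dtype=np.int64)
    np.add.at(nonref, b_pos, b.nonref)
    np.add.at(depth, b_pos, b.depth)
    return SiteReadCounts(site_ids=site_ids, nonref=nonref, depth=depth, library_id=library_id)


def intersect_on_filter(tables: Sequence[FrequencyTable]) -> list[FrequencyTable]:
    """Restrict every table to the sites retained (depth-filtered) in all.

    Implements the "minimum depth in all libraries" rule: the tables already
    carry only their own passing sites, so the common site set is their
    intersection. Order within each table is preserved.
    """
    if len(tables) == 0:
        raise ValueError("need at least one table")
    common = set(tables[0].site_ids)
    for t in tables[1:]:
        common &= set(t.site_ids)
    out = []
    for t in tables:
        mask = np.array([s in common for s in t.site_ids], dtype=bool)
        out.append(t.subset(mask))
    return out


def attach_truth(table: FrequencyTable, panel_site_ids, truth_freq) -> FrequencyTable:
    """Return a copy of ``table`` with truth frequencies joined by site id."""
    lookup = dict(zip(panel_site_ids, np.asarray(truth_freq, dtype=float)))
    missing = [s for s in table.site_ids if s not in lookup]
    if missing:
        raise KeyError(f"no truth frequency for sites {missing[:5]}")
    truth = np.array([lookup[s] for s in table.site_ids])
    return FrequencyTable(
        site_ids=table.site_ids,
        est_freq=table.est_freq,
        depth=table.depth,
        library_id=table.library_id,
        truth_freq=truth,
        min_depth=table.min_depth,
    )
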