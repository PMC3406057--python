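"""SNP discovery from pooled counts and error-rate assessment.

A transparent binomial-test caller stands in for a full genotyper: a site is
called variant when the non-reference count is both above a floor and
unlikely to arise from sequencing error alone. Calls are scored against a
truth panel as false positive / false negative rates by folded-frequency
bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from pooledseq.pool_freq import FrequencyTable
from pooledseq.synthetic_data import SiteReadCounts, StrainPanel

__all__ = [
    "DiscoveryReport",
    "DEFAULT_FOLDED_BINS",
    "call_snps",
    "discovery_error_rates",
    "fold",
    "write_discovery_report",
]

# (0-5%], (5-10%], (10-50%] folded-frequency bins; cut-points follow the
# reported ">5%" and ">10%" thresholds
DEFAULT_FOLDED_BINS: tuple[float, ...] = (0.0, 0.05, 0.10, 0.5)


def fold(freq) -> np.ndarray:
    """Folded (minor) allele frequency min(f, 1 - f)."""
    f = np.asarray(freq, dtype=float)
    return np.minimum(f, 1.0 - f)


def call_snps(
    counts: SiteReadCounts,
    min_nonref: int = 2,
    alpha: float = 1e-3,
    error_rate: float = 1e-3,
) -> np.ndarray:
    """Call variant sites from pooled counts with a binomial error test.

    A site is called iff ``nonref >= min_nonref`` and the upper-tail
    probability P[Binomial(depth, error_rate) >= nonref] is below ``alpha``.
    Returns the called site ids.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not 0 < error_rate < 0.5:
        raise ValueError(f"error_rate must be in (0, 0.5), got {error_rate}")
    tail = stats.binom.sf(counts.nonref - 1, counts.depth, error_rate)
    called = (counts.nonref >= min_nonref) & (tail < alpha)
    return counts.site_ids[called]


@dataclass
class DiscoveryReport:
    """False positive / false negative rates per folded-frequency bin.

    ``fpr[b]`` is the fraction of called sites whose folded *estimated*
    frequency falls in bin b and which are absent from truth; ``fnr[b]`` is
    the fraction of truth-polymorphic sites in bin b (by folded *truth*
    frequency) that were not called. Bins with no eligible sites report NaN
    (absent), not zero.
    """

    bin_edges: np.ndarray
    fpr: np.ndarray
    fnr: np.ndarray
    n_called: np.ndarray
    n_fp: np.ndarray
    n_truth: np.ndarray
    n_fn: np.ndarray
    truth_mode: str = "source-population"
    caller_params: Optional[dict] = None

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def n_tp(self) -> np.ndarray:
        return self.n_truth - self.n_fn


def _bin_of(folded: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Assign folded frequencies to (lo, hi] bins; exact 0 joins the first."""
    idx = np.searchsorted(edges, folded, side="left") - 1
    return np.clip(idx, 0, len(edges) - 2)


def discovery_error_rates(
    calls: Sequence,
    truth: Union[StrainPanel, np.ndarray],
    est: FrequencyTable,
    bins: Sequence[float] = DEFAULT_FOLDED_BINS,
    truth_mode: str = "source-population",
    caller_params: Optional[dict] = None,
) -> DiscoveryReport:
    """Score a called site set against truth by folded-frequency bin.

    ``truth`` is either a :class:`StrainPanel` (its truth frequencies are
    used in ``source-population`` mode, its realised panel frequencies in
    ``pooled-strains-only`` mode) or an explicit per-site truth frequency
    vector aligned with ``est.site_ids``. A truth frequency strictly inside
    (0, 1) marks the site truth-polymorphic (the FNR universe); any positive
    truth frequency — including fixed non-reference — marks the allele
    present, so calls there are not false positives.

    False positives (called but truth-monomorphic) are binned by their
    folded estimated frequency, since they have no informative truth
    frequency; false negatives by folded truth frequency.
    """
    if truth_mode not in ("source-population", "pooled-strains-only"):
        raise ValueError(f"unknown truth_mode {truth_mode!r}")
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bins must be a strictly increasing edge sequence")

    if isinstance(truth, StrainPanel):
        tf_all = truth.truth_freq if truth_mode == "source-population" else truth.panel_freq
        lookup = dict(zip(truth.site_ids, tf_all))
        truth_freq = np.array([lookup[s] for s in est.site_ids])
    else:
        truth_freq = np.asarray(truth, dtype=float)
        if truth_freq.shape[0] != est.n_sites:
            raise ValueError("truth frequency vector must align with est.site_ids")

    called_set = set(np.asarray(calls).tolist())
    called = np.array([s in called_set for s in est.site_ids], dtype=bool)
    # present: any non-reference allele in truth (a call there is not an FP,
    # even when fixed); polymorphic: strictly segregating, the FNR universe
    present = truth_freq > 0.0
    polymorphic = present & (truth_freq < 1.0)

    folded_truth = fold(truth_freq)
    folded_est = fold(est.est_freq)

    nb = len(edges) - 1
    n_called = np.zeros(nb, dtype=np.int64)
    n_fp = np.zeros(nb, dtype=np.int64)
    n_truth = np.zeros(nb, dtype=np.int64)
    n_fn = np.zeros(nb, dtype=np.int64)

    call_bins = _bin_of(folded_est[called], edges)
    fp_flags = ~present[called]
    np.add.at(n_called, call_bins, 1)
    np.add.at(n_fp, call_bins[fp_flags], 1)

    truth_bins = _bin_of(folded_truth[polymorphic], edges)
    fn_flags = ~called[polymorphic]
    np.add.at(n_truth, truth_bins, 1)
    np.add.at(n_fn, truth_bins[fn_flags], 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        fpr = np.where(n_called > 0, n_fp / np.maximum(n_called, 1), np.nan)
        fnr = np.where(n_truth > 0, n_fn / np.maximum(n_truth, 1), np.nan)

    return DiscoveryReport(
        bin_edges=edges,
        fpr=fpr,
        fnr=fnr,
        n_called=n_called,
        n_fp=n_fp,
        n_truth=n_truth,
        n_fn=n_fn,
        truth_mode=truth_mode,
        caller_params=caller_params,
    )


def write_discovery_report(report: DiscoveryReport, path) -> None:
    """TSV: per folded bin, FPR/FNR and the underlying counts."""
    with open(path, "w") as fh:
        fh.write("bin_lo\tbin_hi\tfpr\tfnr\tn_called\tn_fp\tn_truth\tn_fn\n")
        for b in range(report.n_bins):
            fpr = "NA" if np.isnan(report.fpr[b]) else f"{report.fpr[b]:.6f}"
            fnr = "NA" if np.isnan(report.fnr[b]) else f"{report.fnr[b]:.6f}"
            fh.write(
                f"{report.bin_edges[b]:.3f}\t{report.bin_edges[b + 1]:.3f}\t{fpr}\t{fnr}"
                f"\t{report.n_called[b]}\t{report.n_fp[b]}\t{report.n_truth[b]}\t{report.n_fn[b]}\n"
            )
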