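"""Plain-text readers and writers for panels, counts and calls.

Formats
-------
panel TSV       site_id, truth_freq, strain_1..strain_N (0/1 genotypes)
counts TSV      site_id, nonref, depth, library_id
sync            chrom, pos, ref, A:T:C:G:N:del per library — the pooled
                count-pileup convention; a fixed dummy chromosome with
                ref=A, alt=T encodes (depth - nonref, nonref)
VCF             minimal reader for one pooled sample with AD allelic depths
                (biallelic records only), and a minimal writer for called
                sites
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from pooledseq.synthetic_data import SiteReadCounts, StrainPanel

__all__ = [
    "write_panel",
    "read_panel",
    "write_counts",
    "read_counts",
    "write_sync",
    "read_sync",
    "read_vcf_counts",
    "write_vcf_calls",
]

SYNC_CHROM = "sim"


def write_panel(panel: StrainPanel, path) -> None:
    cols = {"site_id": panel.site_ids, "truth_freq": panel.truth_freq}
    for i, sid in enumerate(panel.strain_ids):
        cols[str(sid)] = panel.genotypes[i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_panel(path) -> StrainPanel:
    df = pd.read_csv(path, sep="\t")
    for col in ("site_id", "truth_freq"):
        if col not in df.columns:
            raise ValueError(f"panel file missing required column '{col}'")
    strain_cols = [c for c in df.columns if c not in ("site_id", "truth_freq")]
    if not strain_cols:
        raise ValueError("panel file has no strain genotype columns")
    return StrainPanel(
        genotypes=df[strain_cols].to_numpy().T,
        site_ids=df["site_id"].to_numpy(),
        truth_freq=df["truth_freq"].to_numpy(),
        strain_ids=np.array(strain_cols),
    )


def write_counts(counts: SiteReadCounts, path) -> None:
    pd.DataFrame(
        {
            "site_id": counts.site_ids,
            "nonref": counts.nonref,
            "depth": counts.depth,
            "library_id": counts.library_id,
        }
    ).to_csv(path, sep="\t", index=False)


def read_counts(path) -> SiteReadCounts:
    df = pd.read_csv(path, sep="\t")
    for col in ("site_id", "nonref", "depth"):
        if col not in df.columns:
            raise ValueError(f"counts file missing required column '{col}'")
    lib = str(df["library_id"].iloc[0]) if "library_id" in df.columns and len(df) else "pool"
    return SiteReadCounts(
        site_ids=df["site_id"].to_numpy(),
        nonref=df["nonref"].to_numpy(),
        depth=df["depth"].to_numpy(),
        library_id=lib,
    )


def write_sync(libraries: Sequence[SiteReadCounts], path) -> None:
    """One sync line per site: chrom, pos, ref, then A:T:C:G:N:del per library.

    All libraries must share the same site list; positions are 1-based site
    ordinals on a dummy chromosome, with ref counts in the A slot and
    non-reference counts in the T slot.
    """
    if not libraries:
        raise ValueError("need at least one library")
    first = libraries[0]
    for lib in libraries[1:]:
        if not np.array_equal(lib.site_ids, first.site_ids):
            raise ValueError("sync output requires identical site lists across libraries")
    with open(path, "w") as fh:
        for j in range(first.n_sites):
            cols = [SYNC_CHROM, str(j + 1), "A"]
            for lib in libraries:
                ref = lib.depth[j] - lib.nonref[j]
                cols.append(f"{ref}:{lib.nonref[j]}:0:0:0:0")
            fh.write("\t".join(cols) + "\n")


def read_sync(path, library_ids: Optional[Sequence[str]] = None) -> list[SiteReadCounts]:
    """Parse a sync file into one SiteReadCounts per library column.

    The non-reference count is the depth minus the count of the reference
    base's slot; N and deletion slots are excluded from depth.
    """
    base_slot = {"A": 0, "T": 1, "C": 2, "G": 3}
    site_ids: list[str] = []
    per_lib_nonref: list[list[int]] = []
    per_lib_depth: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"malformed sync line: {line!r}")
            chrom, pos, ref = fields[0], fields[1], fields[2].upper()
            if ref not in base_slot:
                raise ValueError(f"unsupported reference base {ref!r} in sync file")
            site_ids.append(f"{chrom}:{pos}")
            lib_fields = fields[3:]
            if not per_lib_nonref:
                per_lib_nonref = [[] for _ in lib_fields]
                per_lib_depth = [[] for _ in lib_fields]
            elif len(lib_fields) != len(per_lib_nonref):
                raise ValueError("inconsistent library column count in sync file")
            for k, token in enumerate(lib_fields):
                counts = [int(c) for c in token.split(":")]
                if len(counts) != 6:
                    raise ValueError(f"malformed sync count string {token!r}")
                depth = sum(counts[:4])
                per_lib_nonref[k].append(depth - counts[base_slot[ref]])
                per_lib_depth[k].append(depth)
    n_libs = len(per_lib_nonref)
    if library_ids is None:
        library_ids = [f"lib_{k + 1}" for k in range(n_libs)]
    elif len(library_ids) != n_libs:
        raise ValueError(f"expected {n_libs} library ids, got {len(library_ids)}")
    sids = np.array(site_ids)
    return [
        SiteReadCounts(
            site_ids=sids,
            nonref=np.array(per_lib_nonref[k]),
            depth=np.array(per_lib_depth[k]),
            library_id=str(library_ids[k]),
        )
        for k in range(n_libs)
    ]


def read_vcf_counts(path, sample: Optional[str] = None) -> SiteReadCounts:
    """Extract per-site allelic depths from a VCF with AD-format genotypes.

    Biallelic records only; the non-reference count is the ALT allele depth
    and total depth is REF + ALT depth. Requires :mod:`pysam`.
    """
    import pysam  # optional dependency, only needed for real-data mode

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if not samples:
        raise ValueError("VCF has no sample columns")
    if sample is None:
        sample = samples[0]
    elif sample not in samples:
        raise ValueError(f"sample {sample!r} not in VCF (has {samples})")
    site_ids, nonref, depth = [], [], []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        ad = rec.samples[sample].get("AD")
        if ad is None or len(ad) < 2 or ad[0] is None or ad[1] is None:
            continue
        site_ids.append(f"{rec.chrom}:{rec.pos}")
        nonref.append(int(ad[1]))
        depth.append(int(ad[0]) + int(ad[1]))
    return SiteReadCounts(
        site_ids=np.array(site_ids),
        nonref=np.array(nonref, dtype=np.int64),
        depth=np.array(depth, dtype=np.int64),
        library_id=str(sample),
    )


def write_vcf_calls(counts: SiteReadCounts, called_site_ids, path) -> None:
    """Minimal VCF of called sites: REF=A, ALT=T, INFO carries NR/DP."""
    called = set(np.asarray(called_site_ids).tolist())
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={SYNC_CHROM}>\n")
        fh.write('##INFO=<ID=NR,Number=1,Type=Integer,Description="Non-reference read count">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for j, sid in enumerate(counts.site_ids):
            if sid not in called:
                continue
            fh.write(
                f"{SYNC_CHROM}\t{j + 1}\t{sid}\tA\tT\t.\tPASS"
                f"\tNR={counts.nonref[j]};DP={counts.depth[j]}\n"
            )
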