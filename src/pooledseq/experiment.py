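"""End-to-end experiment orchestration: the library family and strain sweep.

Builds a family of simulated pooled libraries from one strain panel — a
small 22-strain pool at 10x, two replicate 42-strain pools at 20x, a
disjoint 50-strain pool at 20x, and merged 42/92-strain pools at 40x — runs
the binned-resampling accuracy experiment on each, and emits a
strains-pooled versus observed/expected concordance table.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from pooledseq.accuracy import (
    AccuracyReport,
    ResampleDesign,
    accuracy_experiment,
    write_accuracy_report,
)
from pooledseq.pool_freq import estimate_frequencies, intersect_on_filter, merge_libraries
from pooledseq.synthetic_data import (
    PoissonDepth,
    PoolDesign,
    SeedLike,
    SiteReadCounts,
    StrainPanel,
    draw_contributions,
    generate_panel,
    simulate_pool_reads,
    split_seeds,
)

__all__ = ["LibrarySpec", "MergeSpec", "ExperimentConfig", "ExperimentResult", "run_library_family"]


@dataclass(frozen=True)
class LibrarySpec:
    """One simulated library: a strain subset, mean depth and contribution model."""

    library_id: str
    strains: Sequence[int]
    depth_mean: float
    concentration: float = math.inf
    error_rate: float = 0.0


@dataclass(frozen=True)
class MergeSpec:
    library_id: str
    parents: tuple[str, str]


@dataclass
class ExperimentConfig:
    n_strains: int = 92
    n_sites: int = 100_000
    sfs: Union[str, Sequence[float]] = "uniform"
    truth: str = "population"
    libraries: list[LibrarySpec] = field(default_factory=list)
    merges: list[MergeSpec] = field(default_factory=list)
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    min_depth: int = 10
    design: ResampleDesign = field(default_factory=ResampleDesign)
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.libraries:
            self.libraries = default_library_family(self.n_strains)
            self.merges = default_merges()
            self.replicate_pairs = [("B1", "B2")]
        self.validate()

    def validate(self) -> None:
        ids = [lib.library_id for lib in self.libraries]
        if len(set(ids)) != len(ids):
            raise ValueError(f"libraries: duplicate library ids in {ids}")
        for lib in self.libraries:
            bad = [s for s in lib.strains if not 0 <= s < self.n_strains]
            if bad:
                raise ValueError(
                    f"libraries[{lib.library_id}].strains: indices {bad[:5]} outside "
                    f"panel of {self.n_strains} strains"
                )
            if lib.depth_mean <= 0:
                raise ValueError(f"libraries[{lib.library_id}].depth_mean: must be > 0")
        known = set(ids)
        for m in self.merges:
            for p in m.parents:
                if p not in known:
                    raise ValueError(f"merges[{m.library_id}].parents: unknown library {p!r}")
            known.add(m.library_id)
        for a, b in self.replicate_pairs:
            for p in (a, b):
                if p not in known:
                    raise ValueError(f"replicate_pairs: unknown library {p!r}")
        if self.truth not in ("population", "panel"):
            raise ValueError("truth: must be 'population' or 'panel'")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed: must be an integer")

    def to_dict(self) -> dict:
        return {
            "n_strains": self.n_strains,
            "n_sites": self.n_sites,
            "sfs": self.sfs if isinstance(self.sfs, str) else list(self.sfs),
            "truth": self.truth,
            "libraries": [
                {
                    "library_id": lib.library_id,
                    "strains": list(map(int, lib.strains)),
                    "depth_mean": lib.depth_mean,
                    "concentration": "inf" if math.isinf(lib.concentration) else lib.concentration,
                    "error_rate": lib.error_rate,
                }
                for lib in self.libraries
            ],
            "merges": [
                {"library_id": m.library_id, "parents": list(m.parents)} for m in self.merges
            ],
            "replicate_pairs": [list(p) for p in self.replicate_pairs],
            "min_depth": self.min_depth,
            "n_bins": self.design.n_bins,
            "per_bin": self.design.per_bin,
            "n_reps": self.n_reps,
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        libraries = [
            LibrarySpec(
                library_id=str(d["library_id"]),
                strains=list(d["strains"]) if not isinstance(d["strains"], int)
                else list(range(d["strains"])),
                depth_mean=float(d["depth_mean"]),
                concentration=math.inf
                if str(d.get("concentration", "inf")) in ("inf", "Infinity")
                else float(d.get("concentration", math.inf)),
                error_rate=float(d.get("error_rate", 0.0)),
            )
            for d in raw.get("libraries", [])
        ]
        merges = [
            MergeSpec(library_id=str(d["library_id"]), parents=tuple(d["parents"]))
            for d in raw.get("merges", [])
        ]
        design = ResampleDesign(
            n_bins=int(raw.get("n_bins", 20)),
            bin_width=1.0 / int(raw.get("n_bins", 20)),
            per_bin=int(raw.get("per_bin", 50)),
        )
        return cls(
            n_strains=int(raw.get("n_strains", 92)),
            n_sites=int(raw.get("n_sites", 100_000)),
            sfs=raw.get("sfs", "uniform"),
            truth=raw.get("truth", "population"),
            libraries=libraries,
            merges=merges,
            replicate_pairs=[tuple(p) for p in raw.get("replicate_pairs", [])],
            min_depth=int(raw.get("min_depth", 10)),
            design=design,
            n_reps=int(raw.get("n_reps", 100)),
            seed=int(raw.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def default_library_family(n_strains: int = 92, concentration: float = math.inf) -> list[LibrarySpec]:
    """The pool-size/depth family: 22@10x, two replicate 42@20x, disjoint 50@20x."""
    if n_strains < 92:
        raise ValueError("default family needs a panel of >= 92 strains")
    return [
        LibrarySpec("A", list(range(22)), depth_mean=10, concentration=concentration),
        LibrarySpec("B1", list(range(42)), depth_mean=20, concentration=concentration),
        LibrarySpec("B2", list(range(42)), depth_mean=20, concentration=concentration),
        LibrarySpec("B4", list(range(42, 92)), depth_mean=20, concentration=concentration),
    ]


def default_merges() -> list[MergeSpec]:
    return [
        MergeSpec("B3", ("B1", "B2")),
        MergeSpec("B5", ("B1", "B4")),
        MergeSpec("B6", ("B2", "B4")),
    ]


@dataclass
class ExperimentResult:
    panel: StrainPanel
    counts: dict[str, SiteReadCounts]
    n_strains_pooled: dict[str, int]
    reports: dict[str, AccuracyReport]
    replicate_reports: dict[str, AccuracyReport]
    timings: dict[str, float]

    def sweep_table(self) -> list[dict]:
        """Strains-pooled vs observed/expected concordance, one row per library."""
        rows = []
        for lib_id, rep in self.reports.items():
            obs_lo, obs_hi = rep.range("observed_ccc")
            exp_lo, exp_hi = rep.range("expected_ccc")
            rows.append(
                {
                    "library_id": lib_id,
                    "n_strains": self.n_strains_pooled[lib_id],
                    "observed_ccc_min": obs_lo,
                    "observed_ccc_max": obs_hi,
                    "observed_ccc_mean": float(rep.observed_ccc.mean()),
                    "expected_ccc_min": exp_lo,
                    "expected_ccc_max": exp_hi,
                    "expected_ccc_mean": float(rep.expected_ccc.mean()),
                }
            )
        rows.sort(key=lambda r: (r["n_strains"], r["library_id"]))
        return rows


def run_library_family(
    config: ExperimentConfig, outdir: Optional[Path] = None, seed: SeedLike = None
) -> ExperimentResult:
    """Simulate the configured library family and evaluate accuracy on each.

    Merged libraries sum the read counts of their parents. Every library is
    scored against the panel's truth frequencies; configured replicate pairs
    additionally get replicate-mode reports. With ``outdir`` set, per-library
    report TSVs, the sweep table and a resolved config copy are written.
    """
    seed = config.seed if seed is None else seed
    rng_panel, rng_libs, rng_acc = split_seeds(seed, 3)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    panel = generate_panel(
        config.n_strains, config.n_sites, sfs=config.sfs, seed=rng_panel, truth=config.truth
    )
    timings["panel"] = time.perf_counter() - t0

    counts: dict[str, SiteReadCounts] = {}
    n_pooled: dict[str, int] = {}
    lib_rngs = split_seeds(rng_libs, len(config.libraries))
    for lib, rng in zip(config.libraries, lib_rngs):
        t0 = time.perf_counter()
        idx = np.asarray(list(lib.strains), dtype=np.int64)
        sub = panel.subset_strains(idx)
        weights = draw_contributions(idx.size, lib.concentration, seed=rng)
        design = PoolDesign(
            weights=weights,
            depth_model=PoissonDepth(lib.depth_mean),
            error_rate=lib.error_rate,
            min_depth=config.min_depth,
        )
        counts[lib.library_id] = simulate_pool_reads(
            sub, design, seed=rng, library_id=lib.library_id
        )
        n_pooled[lib.library_id] = idx.size
        timings[f"simulate[{lib.library_id}]"] = time.perf_counter() - t0

    for m in config.merges:
        t0 = time.perf_counter()
        a, b = (counts[p] for p in m.parents)
        counts[m.library_id] = merge_libraries(a, b, library_id=m.library_id)
        n_pooled[m.library_id] = len(
            {s for p in m.parents for s in _strain_set(config, p)}
        )
        timings[f"merge[{m.library_id}]"] = time.perf_counter() - t0

    reports: dict[str, AccuracyReport] = {}
    tables = {}
    acc_rngs = split_seeds(rng_acc, len(counts) + len(config.replicate_pairs))
    for (lib_id, c), rng in zip(counts.items(), acc_rngs[: len(counts)]):
        t0 = time.perf_counter()
        table = estimate_frequencies(c, config.min_depth, truth_freq=panel.truth_freq)
        tables[lib_id] = table
        reports[lib_id] = accuracy_experiment(
            table, mode="vs_truth", design=config.design, n_reps=config.n_reps, seed=rng
        )
        timings[f"accuracy[{lib_id}]"] = time.perf_counter() - t0

    replicate_reports: dict[str, AccuracyReport] = {}
    for (a, b), rng in zip(config.replicate_pairs, acc_rngs[len(counts) :]):
        t0 = time.perf_counter()
        ta, tb = intersect_on_filter([tables[a], tables[b]])
        replicate_reports[f"{a}|{b}"] = accuracy_experiment(
            ta,
            mode="replicate",
            est_table_2=tb,
            design=config.design,
            n_reps=config.n_reps,
            seed=rng,
        )
        timings[f"replicate[{a}|{b}]"] = time.perf_counter() - t0

    result = ExperimentResult(
        panel=panel,
        counts=counts,
        n_strains_pooled=n_pooled,
        reports=reports,
        replicate_reports=replicate_reports,
        timings=timings,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        resolved = config.to_dict()
        resolved["seed"] = int(seed) if isinstance(seed, (int, np.integer)) else resolved["seed"]
        with open(outdir / "config.resolved.yaml", "w") as fh:
            yaml.safe_dump(resolved, fh, sort_keys=False)
        for lib_id, rep in reports.items():
            write_accuracy_report(rep, outdir / f"accuracy_{lib_id}.tsv")
        for pair_id, rep in replicate_reports.items():
            write_accuracy_report(rep, outdir / f"replicate_{pair_id.replace('|', '_vs_')}.tsv")
        _write_sweep(result.sweep_table(), outdir / "concordance_by_strains.tsv")
    return result


def _strain_set(config: ExperimentConfig, lib_id: str) -> set:
    for lib in config.libraries:
        if lib.library_id == lib_id:
            return set(lib.strains)
    for m in config.merges:
        if m.library_id == lib_id:
            return {s for p in m.parents for s in _strain_set(config, p)}
    raise KeyError(lib_id)


def _write_sweep(rows: list[dict], path) -> None:
    cols = [
        "library_id",
        "n_strains",
        "observed_ccc_min",
        "observed_ccc_max",
        "observed_ccc_mean",
        "expected_ccc_min",
        "expected_ccc_max",
        "expected_ccc_mean",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    str(row[c]) if c in ("library_id", "n_strains") else f"{row[c]:.6f}"
                    for c in cols
                )
                + "\n"
            )
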