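"""Synthetic amplicon-coverage batches with known CNV truth.

The generator emulates the structure of a multiplex-PCR targeted panel run:

* a panel of genes split across chromosomes (including an X pair for sex
  dosage and a "chr21" gene pair as the whole-chromosome-gain stand-in),
  amplicons interleaved over primer pools;
* a per-amplicon amplification efficiency (log-normal — the dominant source
  of between-amplicon depth spread in multiplex PCR);
* per-sample library size and per-(sample, pool) mixing imbalance
  (log-normal factors);
* copy dosage: 2 on autosomes, 1/2 on chrX for males/females, and the
  injected CNV events' copy numbers;
* count noise: Poisson, negative binomial (default; dispersion set so the
  coefficient of variation is ~15% at depth 500), or none — the "none" mode
  returns the exact expected depths so closed-form pipeline checks hold to
  machine precision.

Expected depth of amplicon *a* in sample *s*:

    E[x_as] = depth_s * eff_a * poolfactor_{s,pool(a)} * dosage_as / 2
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .io import AmpliconDataset, join_and_validate

X_GENE_NAMES = ["POU3F4", "SMPX", "PRPS1", "COL4A5"]
CHR21_GENE_NAMES = ["CLDN14", "TMPRSS3"]


@dataclass
class CnvEvent:
    """One ground-truth copy-number event.

    The event targets either a ``gene`` or a whole ``chrom``; ``first`` /
    ``last`` (0-based indices into the unit's amplicons, inclusive) restrict
    it to a sub-range, default the whole unit. ``copy_number`` is the true
    total copy count (2 is diploid and therefore not an event).
    """

    sample_id: str
    copy_number: int
    gene: str | None = None
    chrom: str | None = None
    first: int | None = None
    last: int | None = None

    def __post_init__(self):
        if self.copy_number < 0 or self.copy_number == 2:
            raise ValueError(f"event copy number must be >=0 and != 2, got {self.copy_number}")
        if (self.gene is None) == (self.chrom is None):
            raise ValueError("event must name exactly one of gene or chrom")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated batch.

    Defaults follow the real workflow's geometry: 45-sample batches (one
    sequencing run), a 20-gene x 15-amplicon panel over 2 interleaved primer
    pools with two chrX genes and a two-gene "chr21", mean depth 500 reads,
    negative-binomial counts with dispersion 50 (CV ~ 15% at depth 500).
    """

    n_samples: int = 45
    n_genes: int = 20
    amplicons_per_gene: int = 15
    n_pools: int = 2
    n_x_genes: int = 2
    n_chr21_genes: int = 2
    mean_depth: float = 500.0
    sample_depth_sigma: float = 0.2
    efficiency_sigma: float = 0.5
    pool_imbalance_sigma: float = 0.15
    pool_imbalance_factor: float = 1.0
    noise: str = "negative_binomial"   # "negative_binomial" | "poisson" | "none"
    dispersion: float = 50.0
    events: list[CnvEvent] = field(default_factory=list)
    sexes: str | list[str] = "balanced"  # "balanced" | "all_female" | "all_male" | list
    expect_analyzable: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples per batch")
        if self.noise not in ("negative_binomial", "poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.n_x_genes + self.n_chr21_genes > self.n_genes:
            raise ValueError("more special genes than genes in the panel")


@dataclass
class SimTruth:
    """Ground truth for a simulated batch: events plus per-sample expectations."""

    events: pd.DataFrame        # sample_id, gene, chrom, first/last amplicon, copy_number
    sexes: pd.Series            # per sample
    expect_analyzable: pd.Series


def build_panel(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic panel design for a config (no randomness involved).

    Autosomal genes cycle over chr1..chr20 (10 Mb apart when sharing a
    chromosome); the gene landing on chr15 is named STRC in honor of the
    locus this class of panel is built around. Amplicons are 250 bp, 300 bp
    apart, pools interleaved by position.
    """
    n_auto = config.n_genes - config.n_x_genes - config.n_chr21_genes
    genes: list[tuple[str, str]] = []
    strc_named = False
    for i in range(n_auto):
        chrom = f"chr{(i % 20) + 1}"
        if chrom == "chr15" and not strc_named:
            name = "STRC"
            strc_named = True
        else:
            name = f"GENE{i + 1:03d}"
        genes.append((name, chrom))
    for i in range(config.n_chr21_genes):
        name = CHR21_GENE_NAMES[i] if i < len(CHR21_GENE_NAMES) else f"G21_{i + 1}"
        genes.append((name, "chr21"))
    for i in range(config.n_x_genes):
        name = X_GENE_NAMES[i] if i < len(X_GENE_NAMES) else f"GX_{i + 1}"
        genes.append((name, "chrX"))

    per_chrom_rank: dict[str, int] = {}
    records = []
    for gene, chrom in genes:
        rank = per_chrom_rank.get(chrom, 0)
        per_chrom_rank[chrom] = rank + 1
        offset = 1_000_000 + rank * 10_000_000
        for j in range(config.amplicons_per_gene):
            start = offset + j * 300
            records.append(
                (
                    f"AMPL_{gene}_{j + 1:03d}",
                    chrom,
                    start,
                    start + 250,
                    gene,
                    (j % config.n_pools) + 1,
                )
            )
    design = pd.DataFrame.from_records(
        records, columns=["amplicon_id"] + cio.DESIGN_COLUMNS
    ).set_index("amplicon_id")
    return design


def _resolve_sexes(config: SimulationConfig, sample_ids: list[str]) -> pd.Series:
    if isinstance(config.sexes, str):
        if config.sexes == "balanced":
            vals = ["female" if i % 2 == 0 else "male" for i in range(len(sample_ids))]
        elif config.sexes in ("all_female", "all_male"):
            vals = [config.sexes.removeprefix("all_")] * len(sample_ids)
        else:
            raise ValueError(f"unknown sexes spec {config.sexes!r}")
    else:
        if len(config.sexes) != len(sample_ids):
            raise ValueError("sexes list length must equal n_samples")
        vals = list(config.sexes)
    return pd.Series(vals, index=sample_ids, name="sex")


def _dosage_matrix(
    config: SimulationConfig,
    design: pd.DataFrame,
    sample_ids: list[str],
    sexes: pd.Series,
) -> tuple[np.ndarray, pd.DataFrame]:
    D = np.full((len(design), len(sample_ids)), 2.0)
    is_x = (design["chrom"] == "chrX").to_numpy()
    for k, s in enumerate(sample_ids):
        if sexes[s] == "male":
            D[is_x, k] = 1.0
    resolved = []
    sample_pos = {s: k for k, s in enumerate(sample_ids)}
    for ev in config.events:
        if ev.sample_id not in sample_pos:
            raise ValueError(f"event sample {ev.sample_id!r} not in batch")
        if ev.gene is not None:
            unit = np.flatnonzero((design["gene"] == ev.gene).to_numpy())
            if unit.size == 0:
                raise ValueError(f"event gene {ev.gene!r} not in panel")
        else:
            unit = np.flatnonzero((design["chrom"] == ev.chrom).to_numpy())
            if unit.size == 0:
                raise ValueError(f"event chromosome {ev.chrom!r} not in panel")
        first = 0 if ev.first is None else ev.first
        last = unit.size - 1 if ev.last is None else ev.last
        if not (0 <= first <= last < unit.size):
            raise ValueError(
                f"event range [{ev.first}, {ev.last}] outside unit of {unit.size} amplicons"
            )
        rows = unit[first : last + 1]
        D[rows, sample_pos[ev.sample_id]] = float(ev.copy_number)
        resolved.append(
            {
                "sample_id": ev.sample_id,
                "gene": ev.gene if ev.gene is not None else "",
                "chrom": design.iloc[rows[0]]["chrom"],
                "first_amplicon": design.index[rows[0]],
                "last_amplicon": design.index[rows[-1]],
                "n_amplicons": len(rows),
                "copy_number": ev.copy_number,
            }
        )
    truth_events = pd.DataFrame(
        resolved,
        columns=["sample_id", "gene", "chrom", "first_amplicon",
                 "last_amplicon", "n_amplicons", "copy_number"],
    )
    return D, truth_events


def simulate_batch(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate one batch: (design, depths, sample metadata, truth).

    Fixed seed implies byte-identical output. The returned frames are ready
    for :func:`ampliconcnv.io.join_and_validate`.
    """
    rng = np.random.default_rng(config.seed)
    design = build_panel(config)
    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    sexes = _resolve_sexes(config, sample_ids)

    eff = rng.lognormal(mean=0.0, sigma=config.efficiency_sigma, size=len(design))
    depth_s = config.mean_depth * rng.lognormal(
        mean=0.0, sigma=config.sample_depth_sigma, size=len(sample_ids)
    )
    pool_fac = np.ones((config.n_pools, len(sample_ids)))
    if config.n_pools > 1:
        pool_fac[1:, :] = rng.lognormal(
            mean=0.0, sigma=config.pool_imbalance_sigma,
            size=(config.n_pools - 1, len(sample_ids)),
        )
        pool_fac[1, :] *= config.pool_imbalance_factor

    D, truth_events = _dosage_matrix(config, design, sample_ids, sexes)
    pool_idx = design["pool"].to_numpy() - 1
    expected = (
        eff[:, None] * depth_s[None, :] * pool_fac[pool_idx, :] * D / 2.0
    )

    if config.noise == "none":
        depths_arr = expected
    elif config.noise == "poisson":
        depths_arr = rng.poisson(expected).astype(np.int64)
    else:
        k = config.dispersion
        p = k / (k + expected)
        depths_arr = rng.negative_binomial(k, p).astype(np.int64)

    depths = pd.DataFrame(depths_arr, index=design.index, columns=sample_ids)
    meta = sexes.to_frame()
    truth = SimTruth(
        events=truth_events,
        sexes=sexes,
        expect_analyzable=pd.Series(
            config.expect_analyzable, index=sample_ids, name="expect_analyzable"
        ),
    )
    return design, depths, meta, truth


def simulate_dataset(config: SimulationConfig) -> tuple[AmpliconDataset, SimTruth]:
    """Simulate a batch and join it into a validated dataset."""
    design, depths, meta, truth = simulate_batch(config)
    return join_and_validate(design, depths, meta), truth


FIXTURE_NAMES = [
    "clean_diploid",
    "strc_loss",
    "gain",
    "trisomy",
    "unanalyzable",
    "balanced_sex",
]


def fixture_configs(seed: int = 0) -> dict[str, SimulationConfig]:
    """The canonical six study conditions used throughout the test suite."""
    base = SimulationConfig(sexes="all_female", seed=seed)
    return {
        "clean_diploid": replace(base, seed=seed + 1),
        "strc_loss": replace(
            base,
            seed=seed + 2,
            events=[
                CnvEvent(sample_id="S005", gene="STRC", copy_number=1),
                CnvEvent(sample_id="S010", gene="STRC", copy_number=0),
            ],
        ),
        "gain": replace(
            base,
            seed=seed + 3,
            events=[CnvEvent(sample_id="S007", gene="GENE003", copy_number=3,
                             first=3, last=12)],
        ),
        "trisomy": replace(
            base,
            seed=seed + 4,
            events=[CnvEvent(sample_id="S003", chrom="chr21", copy_number=3)],
        ),
        "unanalyzable": replace(
            base,
            seed=seed + 5,
            dispersion=4.0,
            pool_imbalance_sigma=1.0,
            expect_analyzable=False,
        ),
        "balanced_sex": replace(
            base, seed=seed + 6, n_samples=44, sexes="balanced", noise="none"
        ),
    }


def make_fixture_suite(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the six canonical batches to ``outdir`` (one directory each).

    Each batch directory holds ``design.bed``, ``coverage.tsv``,
    ``samples.tsv`` (sex + analyzability expectation) and ``truth.tsv``
    (every injected event). Deterministic in ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, config in fixture_configs(seed).items():
        d = outdir / name
        d.mkdir(exist_ok=True)
        design, depths, meta, truth = simulate_batch(config)
        cio.write_design_bed(design, d / "design.bed")
        cio.write_coverage_matrix(depths, d / "coverage.tsv")
        meta_out = meta.copy()
        meta_out["expect_analyzable"] = truth.expect_analyzable
        cio.write_sample_meta(meta_out, d / "samples.tsv")
        truth.events.to_csv(d / "truth.tsv", sep="\t", index=False)
        paths[name] = d
    return paths
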