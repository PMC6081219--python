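"""Pool-wise and population-based normalization of amplicon read depths.

The dosage scale is built in four steps, all simple ratios:

1. pool means      x̄_sp = mean of raw depths of pool p in sample s
2. relative depth  r_as = x_as / x̄_{s,pool(a)}
3. batch reference r̄_a  = mean of r_as over the batch's samples
4. normalized      t_as = 2 · r_as / r̄_a

Step 2 cancels per-sample, per-pool library effects (total yield, unequal
pool mixing); step 4 cancels per-amplicon amplification-efficiency effects
using the batch as its own reference, and rescales so that a diploid locus
sits at ~2 copies. Amplicons whose batch-mean relative depth falls at or
below a small threshold (default 0.1) are unreliable ratio denominators and
are masked from all downstream statistics.

Undefined values (division by a zero pool mean or zero reference) propagate
as NaN, never as silent zeros — a true zero is a homozygous-deletion signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AmpliconDataset

logger = logging.getLogger(__name__)


@dataclass
class NormalizedBatch:
    """All intermediate and final matrices of the normalization pipeline."""

    dataset: AmpliconDataset
    pool_means: pd.DataFrame      # samples x pools
    rel: pd.DataFrame             # relative depths, amplicons x samples
    reference: pd.Series          # batch-mean relative depth per amplicon
    norm: pd.DataFrame            # normalized depths (diploid ~ 2)
    retained: pd.Series           # outlier mask (True = kept)
    threshold: float

    @property
    def norm_retained(self) -> pd.DataFrame:
        """Normalized matrix with masked amplicons set to NaN."""
        return self.norm.where(self.retained, np.nan)

    @property
    def batch_size(self) -> int:
        return self.norm.shape[1]


def pool_mean_depths(dataset: AmpliconDataset) -> pd.DataFrame:
    """Mean raw depth per (sample, pool) — the x̄, ȳ of the pool-mean step.

    A pool whose depths are all zero for a sample yields mean 0 (the sample
    is then unanalyzable for that pool: its relative depths become NaN).
    """
    pm = dataset.depths.groupby(dataset.design["pool"]).mean().T
    pm.index.name = "sample_id"
    zero = pm == 0
    if zero.to_numpy().any():
        for sample, row in zero.iterrows():
            for pool in row.index[row]:
                logger.warning(
                    "sample %s: pool %s has zero mean depth; "
                    "flagged unanalyzable for that pool", sample, pool,
                )
    return pm


def relative_depths(dataset: AmpliconDataset, pool_means: pd.DataFrame) -> pd.DataFrame:
    """Depth divided by the sample's mean depth of the amplicon's pool."""
    denom = pool_means.loc[:, dataset.design["pool"]].to_numpy().T  # amp x samp
    with np.errstate(divide="ignore", invalid="ignore"):
        r = dataset.depths.to_numpy(dtype=float) / denom
    r[~np.isfinite(r)] = np.nan
    return pd.DataFrame(r, index=dataset.depths.index, columns=dataset.depths.columns)


def batch_reference(rel: pd.DataFrame) -> pd.Series:
    """Per-amplicon mean relative depth across the batch's samples.

    Requires a batch of at least 2 samples. Samples with undefined values
    for an amplicon are excluded from that amplicon's mean; an amplicon
    undefined in every sample gets a NaN reference (auto-removed downstream).
    """
    if rel.shape[1] < 2:
        raise ValueError(f"batch reference needs >=2 samples, got {rel.shape[1]}")
    return rel.mean(axis=1, skipna=True)


def normalize_depths(rel: pd.DataFrame, reference: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Twofold ratio of relative depth to its batch reference (diploid -> 2)."""
    if isinstance(reference, pd.Series):
        ref = np.broadcast_to(reference.to_numpy()[:, None], rel.shape)
    else:
        ref = reference.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = 2.0 * rel.to_numpy() / ref
    t[~np.isfinite(t)] = np.nan
    return pd.DataFrame(t, index=rel.index, columns=rel.columns)


def filter_low_coverage(reference: pd.Series, threshold: float = 0.1) -> pd.Series:
    """Outlier mask: keep amplicons with batch-mean relative depth > threshold.

    The boundary is inclusive on the removal side (reference <= threshold is
    masked). Undefined references are masked too.
    """
    if threshold < 0:
        raise ValueError(f"outlier threshold must be >= 0, got {threshold}")
    retained = (reference > threshold) & reference.notna()
    retained.name = "retained"
    return retained


def _per_sample_reference(
    rel: pd.DataFrame,
    meta: pd.DataFrame | None,
    sex_aware: bool,
    leave_one_out: bool,
) -> pd.DataFrame:
    """Reference matrix (amplicons x samples) for the configured mode."""
    samples = rel.columns

    def group_ref(cols: pd.Index) -> tuple[pd.Series, pd.Series]:
        sub = rel[cols]
        return sub.sum(axis=1, skipna=True), sub.notna().sum(axis=1)

    if sex_aware:
        if meta is None:
            raise ValueError("sex_aware normalization requires sample metadata")
        sexes = pd.Series(
            [meta["sex"].get(s, "unknown") for s in samples], index=samples
        )
        group_stats = {
            sex: group_ref(samples[(sexes == sex).to_numpy()])
            for sex in ("male", "female")
            if (sexes == sex).any()
        }
    else:
        sexes = pd.Series("unknown", index=samples)
        group_stats = {}

    ref = pd.DataFrame(index=rel.index, columns=samples, dtype=float)
    all_sum, all_n = group_ref(samples)
    for s in samples:
        gsum, gn = group_stats.get(sexes[s], (all_sum, all_n))
        if leave_one_out:
            r_s = rel[s]
            n_eff = gn - r_s.notna().astype(int)
            with np.errstate(invalid="ignore"):
                col = (gsum - r_s.fillna(0.0)) / n_eff.replace(0, np.nan)
        else:
            col = gsum / gn.replace(0, np.nan)
        ref[s] = col
    return ref


def normalize_batch(
    dataset: AmpliconDataset,
    threshold: float = 0.1,
    sex_aware: bool = False,
    leave_one_out: bool = False,
) -> NormalizedBatch:
    """Run the full four-step normalization plus outlier masking.

    Parameters
    ----------
    threshold
        Batch-mean relative depth at or below which an amplicon is masked.
    sex_aware
        Compute each sample's reference within its own sex group (off by
        default: sex chromosomes are deliberately *not* treated separately,
        so X dosage shows up against the mixed-sex batch average).
    leave_one_out
        Exclude the query sample itself from its reference.
    """
    pm = pool_mean_depths(dataset)
    rel = relative_depths(dataset, pm)
    reference = batch_reference(rel)
    if sex_aware or leave_one_out:
        ref_matrix = _per_sample_reference(rel, dataset.meta, sex_aware, leave_one_out)
        norm = normalize_depths(rel, ref_matrix)
    else:
        norm = normalize_depths(rel, reference)
    retained = filter_low_coverage(reference, threshold)
    n_masked = int((~retained).sum())
    if n_masked:
        logger.info("masked %d low-coverage amplicon(s) at threshold %g",
                    n_masked, threshold)
    return NormalizedBatch(
        dataset=dataset,
        pool_means=pm,
        rel=rel,
        reference=reference,
        norm=norm,
        retained=retained,
        threshold=threshold,
    )
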