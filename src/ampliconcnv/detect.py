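"""Candidate flagging and copy-state calling on normalized depth profiles.

The workflow mirrors what an analyst does with the per-gene depth plots:

* sort retained amplicons in genomic order and smooth with a centered
  5-amplicon moving mean (restricted within each gene — targeted panels
  have megabase gaps between genes, so a window must never straddle one);
* flag amplicons whose normalized depth deviates from the sample mean by
  more than one standard deviation;
* slide a 5-amplicon window along each chromosome and Welch-t-test the
  window against the rest of the sample's amplicons;
* merge runs of amplicons whose smoothed dosage sits in one non-diploid
  copy-state band into explicit calls.

The copy-state bands are midpoint cuts of the dosage scale (diploid = 2):
[0, 0.5) -> 0, [0.5, 1.5) -> 1, [1.5, 2.5] -> 2 (no call), (2.5, 3.5] -> 3,
above 3.5 -> 4 (meaning "4 or more").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .io import CALL_COLUMNS, chrom_sort_key
from .normalize import NormalizedBatch

logger = logging.getLogger(__name__)

DIPLOID_STATE = 2


def copy_state(value: float) -> int:
    """Copy-state band of a smoothed dosage value (diploid band -> 2)."""
    if np.isnan(value):
        return -1
    if value < 0.5:
        return 0
    if value < 1.5:
        return 1
    if value <= 2.5:
        return 2
    if value <= 3.5:
        return 3
    return 4


_copy_state_vec = np.vectorize(copy_state, otypes=[int])


def smooth(
    norm: pd.DataFrame,
    design: pd.DataFrame,
    retained: pd.Series,
    window: int = 5,
) -> pd.DataFrame:
    """Centered moving mean over retained amplicons within each (chrom, gene).

    At group edges the window truncates to the amplicons available in the
    gene (a 3-amplicon gene under a 5-wide window smooths every position
    with all 3 values). Masked amplicons stay NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be an odd positive integer, got {window}")
    out = pd.DataFrame(np.nan, index=norm.index, columns=norm.columns)
    kept = design.loc[retained.reindex(design.index).fillna(False)]
    for (_, _), group in kept.groupby(["chrom", "gene"], sort=False):
        idx = group.index
        block = norm.loc[idx]
        out.loc[idx] = (
            block.rolling(window, center=True, min_periods=1).mean().to_numpy()
        )
    return out


def flag_sd_candidates(
    norm: pd.DataFrame,
    retained: pd.Series,
    sd_multiplier: float = 1.0,
    ddof: int = 0,
) -> pd.DataFrame:
    """Flag amplicons deviating from the sample mean by > multiplier x SD.

    The standard deviation is the population formula (ddof=0) by default,
    computed per sample over its retained amplicons. A zero-SD sample yields
    no flags; a sample with fewer than 2 retained values is skipped with a
    warning.
    """
    vals = norm.where(retained, np.nan)
    counts = vals.notna().sum(axis=0)
    mu = vals.mean(axis=0, skipna=True)
    sigma = vals.std(axis=0, ddof=ddof, skipna=True)
    flags = (vals.sub(mu, axis=1).abs() > sd_multiplier * sigma) & vals.notna()
    thin = counts < 2
    if thin.any():
        logger.warning(
            "no SD flags for sample(s) with <2 retained amplicons: %s",
            list(counts.index[thin]),
        )
        flags.loc[:, thin] = False
    return flags


def _welch_p(m1, v1, n1, m2, v2, n2):
    """Two-sided Welch t-test p-values, vectorized, with zero-variance limits."""
    m1, v1, m2, v2 = (np.asarray(a, dtype=float) for a in (m1, v1, m2, v2))
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    if np.any(degenerate):
        p = np.where(degenerate, np.where(m1 == m2, 1.0, 0.0), p)
    return p


def window_t_test(
    norm: pd.DataFrame,
    design: pd.DataFrame,
    retained: pd.Series,
    window: int = 5,
    exclude_window: bool = True,
    mode: str = "two_sample",
) -> pd.DataFrame:
    """Sliding-window t-test of local dosage vs the sample-wide distribution.

    For every run of ``window`` contiguous retained amplicons within one
    chromosome, test the window's normalized depths against all of the
    sample's retained depths; the two-sided p-value is assigned to the
    window's center amplicon (NaN elsewhere).

    ``mode='two_sample'`` (default) is a Welch unequal-variance test with
    the window excluded from the background unless ``exclude_window=False``;
    ``mode='one_sample'`` tests the window's mean against the background
    mean using the window's own variance. Windows with zero variance in both
    groups take the limit convention p = 1 when the means agree, else 0.
    """
    if mode not in ("two_sample", "one_sample"):
        raise ValueError(f"unknown t-test mode {mode!r}")
    if window < 2:
        raise ValueError(f"t-test window must be >= 2, got {window}")
    pvals = pd.DataFrame(np.nan, index=norm.index, columns=norm.columns)
    kept = design.loc[retained.reindex(design.index).fillna(False)]
    chrom_groups = [
        (chrom, list(g.index)) for chrom, g in kept.groupby("chrom", sort=False)
    ]
    half = window // 2
    for s in norm.columns:
        col = norm[s]
        defined = col.loc[kept.index].dropna()
        n_tot = len(defined)
        if n_tot < window:
            logger.warning(
                "sample %s: only %d retained amplicons (<%d); no t-test windows",
                s, n_tot, window,
            )
            continue
        tot_sum = float(defined.sum())
        tot_sq = float((defined**2).sum())
        any_window = False
        for _, idx in chrom_groups:
            ids = [a for a in idx if not np.isnan(col[a])]
            vals = col.loc[ids].to_numpy(dtype=float)
            if len(vals) < window:
                continue
            any_window = True
            W = sliding_window_view(vals, window)
            wsum = W.sum(axis=1)
            wsq = (W**2).sum(axis=1)
            m1 = wsum / window
            v1 = (wsq - window * m1**2) / (window - 1)
            v1 = np.maximum(v1, 0.0)  # guard tiny negative rounding
            if exclude_window:
                n2 = n_tot - window
                if n2 < 2:
                    continue
                m2 = (tot_sum - wsum) / n2
                v2 = (tot_sq - wsq - n2 * m2**2) / (n2 - 1)
                v2 = np.maximum(v2, 0.0)
            else:
                n2 = n_tot
                m2 = np.full_like(m1, tot_sum / n_tot)
                v2 = np.full_like(
                    m1, max((tot_sq - n_tot * (tot_sum / n_tot) ** 2) / (n_tot - 1), 0.0)
                )
            if mode == "two_sample":
                p = _welch_p(m1, v1, window, m2, v2, n2)
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = (m1 - m2) / np.sqrt(v1 / window)
                    p = 2.0 * stats.t.sf(np.abs(t), window - 1)
                p = np.where(v1 == 0, np.where(m1 == m2, 1.0, 0.0), p)
            centers = [ids[i + half] for i in range(len(m1))]
            pvals.loc[centers, s] = p
        if not any_window:
            logger.warning("sample %s: no chromosome holds %d contiguous retained "
                           "amplicons; no t-test windows", s, window)
    return pvals


def apply_bh(pvals: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg adjust window p-values within each sample."""
    from statsmodels.stats.multitest import multipletests

    out = pvals.copy()
    for s in out.columns:
        mask = out[s].notna()
        if mask.any():
            out.loc[mask, s] = multipletests(out.loc[mask, s], method="fdr_bh")[1]
    return out


def _cluster_positions(pos: np.ndarray, merge_gap: int) -> list[list[int]]:
    """Group sorted positions into [start, end] clusters bridging small gaps."""
    clusters: list[list[int]] = []
    for p in pos:
        if clusters and p - clusters[-1][1] - 1 <= merge_gap:
            clusters[-1][1] = int(p)
        else:
            clusters.append([int(p), int(p)])
    return clusters


def _refine_boundary(
    values: np.ndarray,
    u_states: np.ndarray,
    a: int,
    b: int,
    state: int,
    reach: int,
    side: str,
    center: float | None = None,
    dip_level: float = 2.0,
) -> int:
    """Least-squares changepoint placement of one run boundary.

    Within ``reach`` positions of the smoothed-run edge, choose the boundary
    minimizing the squared error of a step profile (the sample's diploid
    level outside the run, the run's own level inside), using the
    *unsmoothed* values — smoothing blurs event edges by up to half a
    window, the raw per-amplicon dosages carry the sharp step. Outward
    search stops at a barrier: an amplicon whose own dosage band is neither
    diploid nor the run's state (it belongs to some other event, e.g. the
    homozygous core flanked by single-copy smoothing shoulders).

    ``center`` / ``dip_level`` allow empirically estimated step levels: a
    carrier's event inflates (or deflates) its own pool means and the batch
    reference, so the observed levels sit closer to diploid than the ideal
    integer dosages.
    """
    if center is None:
        center = float(state)
    # Count noise scales with dosage (NB variance ~ mu^2/k), so weight the
    # squared error by 1/level^2 (floored for the zero-copy band, whose
    # observed depths are essentially exact zeros).
    w_event = 1.0 / max(center, 0.5) ** 2
    w_dip = 1.0 / max(dip_level, 0.5) ** 2
    # Outward search stops at amplicons whose own band contradicts the run:
    # any band on the opposite side of diploid, plus the zero-copy band when
    # extending a single-copy run (zero depth is a near-noiseless signal of
    # a different, homozygous event).
    barrier = ({0, 1, -1} if state >= 3 else {3, 4, -1}) | (
        {0} if state == 1 else set()
    )
    if side == "left":
        lo = max(0, a - reach)
        for k in range(a - 1, lo - 1, -1):
            if u_states[k] in barrier:
                lo = k + 1
                break
        hi = min(a + reach, b)
        seg = values[lo : hi + 1]
        event_cost = np.concatenate([[0.0], np.cumsum(w_event * (seg - center) ** 2)])
        dip_cost = np.concatenate([[0.0], np.cumsum(w_dip * (seg - dip_level) ** 2)])
        total = event_cost[-1]
        # boundary j: positions < j diploid, >= j event
        costs = [dip_cost[j] + (total - event_cost[j]) for j in range(len(seg))]
        return lo + int(np.argmin(costs))
    else:
        hi = min(len(values) - 1, b + reach)
        for k in range(b + 1, hi + 1):
            if u_states[k] in barrier:
                hi = k - 1
                break
        lo = max(b - reach, a)
        seg = values[lo : hi + 1]
        event_cost = np.concatenate([[0.0], np.cumsum(w_event * (seg - center) ** 2)])
        dip_cost = np.concatenate([[0.0], np.cumsum(w_dip * (seg - dip_level) ** 2)])
        total_dip = dip_cost[-1]
        # boundary j: positions <= j event, > j diploid
        costs = [
            event_cost[j + 1] + (total_dip - dip_cost[j + 1])
            for j in range(len(seg))
        ]
        return lo + int(len(seg) - 1 - np.argmin(costs[::-1]))  # outermost argmin


def call_segments(
    norm: pd.DataFrame,
    smoothed: pd.DataFrame,
    design: pd.DataFrame,
    retained: pd.Series,
    flags: pd.DataFrame | None = None,
    pvalues: pd.DataFrame | None = None,
    min_run: int = 3,
    merge_gap: int = 2,
    refine_reach: int = 5,
) -> pd.DataFrame:
    """Merge runs of same-band smoothed amplicons into explicit CNV calls.

    A call is a run of >= ``min_run`` contiguous retained amplicons
    (contiguity in retained genomic rank, within one chromosome) assigned to
    one non-diploid copy-state band. Candidate runs come from the *smoothed*
    profile (robust to single-amplicon noise); their boundaries are then
    refined on the unsmoothed values with a local least-squares changepoint
    (see :func:`_refine_boundary`) because smoothing blurs edges by up to
    half a window. Same-state runs separated by at most ``merge_gap``
    amplicons are bridged — isolated blips shorter than the smoothing
    half-window are smoothing artifacts a manual curator would skip over.

    Reported per call: genomic extent (1-based inclusive), mean *unsmoothed*
    normalized depth, copy state, whether at least half of the run's
    amplicons carry the +-1 SD flag, and the smallest window-t-test p-value
    whose center lies in the run.
    """
    kept = design.loc[retained.reindex(design.index).fillna(False)]
    chroms = sorted(kept["chrom"].unique(), key=chrom_sort_key)
    rows = []
    for s in norm.columns:
        col_all = norm.loc[kept.index, s]
        # robust estimate of this sample's observed diploid level; a large
        # event shifts the whole profile via the sample's own pool means
        dip_level = float(col_all.median(skipna=True))
        if copy_state(dip_level) != DIPLOID_STATE:
            dip_level = 2.0
        for chrom in chroms:
            ids = [
                a for a in kept.index[kept["chrom"] == chrom]
                if not (np.isnan(smoothed.at[a, s]) or np.isnan(norm.at[a, s]))
            ]
            if not ids:
                continue
            values = norm.loc[ids, s].to_numpy(dtype=float)
            sm_states = _copy_state_vec(smoothed.loc[ids, s].to_numpy(dtype=float))
            u_states = _copy_state_vec(values)
            runs: list[tuple[int, int, int]] = []
            for state in (0, 1, 3, 4):
                pos = np.flatnonzero(sm_states == state)
                if pos.size == 0:
                    continue
                refined = []
                for a, b in _cluster_positions(pos, merge_gap):
                    center = float(np.median(values[a : b + 1]))
                    if copy_state(center) != state:
                        center = float(state)  # cluster too mixed to trust
                    a2 = _refine_boundary(values, u_states, a, b, state,
                                          refine_reach, "left",
                                          center=center, dip_level=dip_level)
                    b2 = _refine_boundary(values, u_states, a, b, state,
                                          refine_reach, "right",
                                          center=center, dip_level=dip_level)
                    if a2 <= b2:
                        refined.append([a2, b2])
                # union same-state intervals (refinement may have extended
                # neighbouring clusters into overlap or near-contact)
                refined.sort()
                unioned: list[list[int]] = []
                for a2, b2 in refined:
                    if unioned and a2 - unioned[-1][1] - 1 <= merge_gap:
                        unioned[-1][1] = max(unioned[-1][1], b2)
                    else:
                        unioned.append([a2, b2])
                # aneuploidy snap: a run covering most of a multi-gene
                # chromosome that stops within the bridging distance of a
                # terminal is read as the whole-chromosome event (the
                # trisomy signature: consistent elevation across genes);
                # single-gene runs stay gene-level CNVs
                n_chrom = len(ids)
                gene_arr = kept.loc[ids, "gene"].to_numpy()
                for iv in unioned:
                    spans_genes = len(set(gene_arr[iv[0] : iv[1] + 1])) >= 2
                    if spans_genes and iv[1] - iv[0] + 1 >= 0.8 * n_chrom:
                        if iv[0] <= merge_gap:
                            iv[0] = 0
                        if n_chrom - 1 - iv[1] <= merge_gap:
                            iv[1] = n_chrom - 1
                runs.extend((state, a2, b2) for a2, b2 in unioned)
            runs.sort(key=lambda r: r[1])
            for state, a, b in runs:
                span = ids[a : b + 1]
                if len(span) < min_run:
                    continue
                genes = list(dict.fromkeys(kept.loc[span, "gene"]))
                sd_flag = (
                    bool(flags.loc[span, s].mean() >= 0.5)
                    if flags is not None
                    else False
                )
                pmin = (
                    float(pvalues.loc[span, s].min(skipna=True))
                    if pvalues is not None and pvalues.loc[span, s].notna().any()
                    else np.nan
                )
                rows.append(
                    {
                        "sample_id": s,
                        "chrom": chrom,
                        "gene": ",".join(genes),
                        "first_amplicon": span[0],
                        "last_amplicon": span[-1],
                        "n_amplicons": len(span),
                        "start": int(kept.at[span[0], "start"]) + 1,
                        "end": int(kept.at[span[-1], "end"]),
                        "copy_state": state,
                        "mean_norm_depth": float(norm.loc[span, s].mean(skipna=True)),
                        "sd_flag": sd_flag,
                        "t_p_value": pmin,
                    }
                )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def batch_qc(
    nb: NormalizedBatch,
    qc_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-sample dispersion QC of the normalized profile.

    Reports the normal-scaled median absolute deviation of each sample's
    retained normalized depths; samples with MAD above ``qc_threshold`` are
    marked unanalyzable (the batch-failure mode: scattered profiles, mostly
    from large pool-1/pool-2 imbalance or overdispersed counts). The raw
    pool-mean ratio (pool 1 / pool 2 for two-pool panels, max/min otherwise)
    is reported alongside.
    """
    vals = nb.norm_retained
    mad = pd.Series(
        stats.median_abs_deviation(
            vals.to_numpy(dtype=float), axis=0, scale="normal", nan_policy="omit"
        ),
        index=vals.columns,
        name="mad",
    )
    pm = nb.pool_means
    pools = sorted(pm.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        if len(pools) == 2:
            ratio = pm[pools[0]] / pm[pools[1]]
        elif len(pools) == 1:
            ratio = pd.Series(1.0, index=pm.index)
        else:
            ratio = pm.max(axis=1) / pm.min(axis=1)
    report = pd.DataFrame(
        {
            "mad": mad,
            "analyzable": mad <= qc_threshold,
            "pool_ratio": ratio.replace([np.inf, -np.inf], np.nan),
        }
    )
    report.index.name = "sample_id"
    return report


@dataclass
class DetectionResult:
    """Bundle of every per-batch detection artifact."""

    smoothed: pd.DataFrame
    flags: pd.DataFrame
    pvalues: pd.DataFrame
    calls: pd.DataFrame
    qc: pd.DataFrame


def detect_cnvs(
    nb: NormalizedBatch,
    window: int = 5,
    min_run: int = 3,
    merge_gap: int = 2,
    sd_multiplier: float = 1.0,
    qc_threshold: float = 0.5,
    bh_correction: bool = False,
    t_test_mode: str = "two_sample",
    exclude_window: bool = True,
    samples: list[str] | None = None,
) -> DetectionResult:
    """Run smoothing, flagging, testing, calling and QC on a normalized batch.

    ``samples`` restricts the per-sample statistics and calls to a subset
    (the batch-level normalization is untouched).
    """
    norm = nb.norm if samples is None else nb.norm[samples]
    design, retained = nb.dataset.design, nb.retained
    smoothed = smooth(norm, design, retained, window=window)
    flags = flag_sd_candidates(norm, retained, sd_multiplier=sd_multiplier)
    pvalues = window_t_test(norm, design, retained, window=window,
                            exclude_window=exclude_window, mode=t_test_mode)
    if bh_correction:
        pvalues = apply_bh(pvalues)
    calls = call_segments(norm, smoothed, design, retained, flags=flags,
                          pvalues=pvalues, min_run=min_run, merge_gap=merge_gap)
    qc = batch_qc(nb, qc_threshold=qc_threshold)
    return DetectionResult(smoothed=smoothed, flags=flags, pvalues=pvalues,
                           calls=calls, qc=qc)
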