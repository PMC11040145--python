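"""Evaluation metrics for low-input methylome data.

Implements the quality metrics used to benchmark detection calling and
low-input workflows: probe success rate, binarized F1 against a
high-input reference (DNA methylation is allelic, so low-cell-number betas
are near-binary and correlation is misleading), Spearman rank correlation,
intermediate-methylation polarization, methylome merging across
single-cell replicates, within-sample intensity Z-scores, and Fisher-exact
probe-set enrichment with BH false-discovery control.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .defaults import DEFAULTS
from .detection import DetectionResult
from .sigset import Manifest

logger = logging.getLogger(__name__)

__all__ = [
    "probe_success_rate",
    "binarize",
    "f1_score",
    "rank_correlation",
    "polarization_fraction",
    "merge_methylomes",
    "intensity_zscore",
    "set_enrichment",
    "mask_jaccard",
]


def probe_success_rate(det: DetectionResult, threshold: float = DEFAULTS["threshold"]) -> float:
    """Fraction of probes with detection p < threshold."""
    p = det.p.to_numpy(dtype=float)
    if len(p) == 0:
        raise ValueError("empty detection result")
    return float(np.mean(p < threshold))


def binarize(betas: pd.Series) -> pd.Series:
    """Round betas to binary calls: 1 iff beta > 0.5 (strict), else 0.

    NaN betas stay NaN.  The strict inequality means beta == 0.5 is a
    0-call.
    """
    b = betas.to_numpy(dtype=float)
    out = np.where(np.isnan(b), np.nan, (b > 0.5).astype(float))
    return pd.Series(out, index=betas.index, name="call")


def f1_score(test: pd.Series, reference: pd.Series) -> float:
    """F1 = 2TP / (2TP + FN + FP) of binary calls, reference 1-calls as truth.

    Only probes defined (non-NaN) in both vectors enter; the exclusion is
    logged.  Returns 0 (with a warning) in the degenerate case with no
    1-calls anywhere.
    """
    t, r = test.align(reference, join="inner")
    ok = t.notna() & r.notna()
    n_excluded = int((~ok).sum()) + len(test.index.symmetric_difference(reference.index))
    if n_excluded:
        logger.info("f1_score: %d probes excluded (undefined in one vector)", n_excluded)
    t = t[ok].to_numpy(dtype=float)
    r = r[ok].to_numpy(dtype=float)
    if len(t) == 0:
        raise ValueError("no probes defined in both vectors")
    tp = float(np.sum((t == 1) & (r == 1)))
    fp = float(np.sum((t == 1) & (r == 0)))
    fn = float(np.sum((t == 0) & (r == 1)))
    denom = 2 * tp + fn + fp
    if denom == 0:
        logger.warning("f1_score: no 1-calls in either vector; returning 0")
        return 0.0
    return 2 * tp / denom


def rank_correlation(test: pd.Series, reference: pd.Series) -> float:
    """Spearman's rho on probes defined in both vectors (midranks for ties)."""
    t, r = test.align(reference, join="inner")
    ok = t.notna() & r.notna()
    t, r = t[ok], r[ok]
    if len(t) < 3:
        raise ValueError("need >= 3 probes defined in both vectors")
    if t.nunique() < 2 or r.nunique() < 2:
        logger.warning("rank_correlation: constant vector; rho undefined")
        return float("nan")
    rho = stats.spearmanr(t, r).statistic
    return float(rho)


def polarization_fraction(
    test: pd.Series,
    reference: pd.Series,
    band: tuple[float, float] = (0.3, 0.7),
) -> float:
    """How dichotomized the test sample is at reference-intermediate CpGs.

    Among probes whose reference beta lies in the closed band, the
    fraction whose test beta falls outside the open band (<= lower or
    >= upper).  Allelic sampling at few cells pushes intermediate
    methylation to 0/1, so this rises as cell number falls.
    """
    lo, hi = band
    t, r = test.align(reference, join="inner")
    eligible = r.notna() & (r >= lo) & (r <= hi) & t.notna()
    if not eligible.any():
        raise ValueError("no probes with intermediate reference beta and defined test beta")
    tv = t[eligible].to_numpy(dtype=float)
    return float(np.mean((tv <= lo) | (tv >= hi)))


def merge_methylomes(betas_list: list[pd.Series]) -> tuple[pd.Series, pd.Series]:
    """Average beta vectors probe-wise across samples.

    Returns (merged, support): per probe the mean of defined betas and the
    number of samples contributing.  Probes defined in no sample are NaN
    with support 0.
    """
    if len(betas_list) < 2:
        raise ValueError("need >= 2 beta vectors to merge")
    df = pd.concat(betas_list, axis=1, join="outer")
    common = betas_list[0].index
    for b in betas_list[1:]:
        common = common.intersection(b.index)
    if len(common) == 0:
        raise ValueError("beta vectors have disjoint probe universes")
    merged = df.mean(axis=1, skipna=True)
    support = df.notna().sum(axis=1)
    merged.name, support.name = "beta", "support"
    return merged, support


def intensity_zscore(log2_totals: pd.Series) -> pd.Series:
    """Within-sample Z-score of per-probe log2 total intensities (ddof=1)."""
    x = log2_totals.to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 probes")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("constant intensities; Z-score undefined")
    z = (x - np.mean(x)) / sd
    return pd.Series(z, index=log2_totals.index, name="z")


def set_enrichment(
    query: set | pd.Index,
    manifest: Manifest,
    universe: set | pd.Index,
    sets: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher-exact enrichment of a probe set query against curated sets.

    For each curated set S (intersected with the universe) builds the 2x2
    table (query∩S, query∖S, S∖query, neither), reports the overlap, the
    log2 odds ratio ad/bc (+0.5 Haldane correction when any cell is zero),
    the two-sided Fisher exact p and the BH-adjusted FDR across all tested
    sets.
    """
    universe = pd.Index(sorted(set(universe)))
    query = pd.Index(sorted(set(query)))
    if len(query) == 0 or len(universe) == 0:
        raise ValueError("query and universe must be non-empty")
    if not query.isin(universe).all():
        raise ValueError("query must be a subset of the universe")
    labels = sets if sets is not None else manifest.set_universe()
    rows = []
    for label in labels:
        members = manifest.probes_in_set(label).intersection(universe)
        a = len(query.intersection(members))
        b = len(query) - a
        c = len(members) - a
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        cells = np.array([a, b, c, d], dtype=float)
        if (cells == 0).any():
            cells = cells + 0.5
        log2_or = float(np.log2((cells[0] * cells[3]) / (cells[1] * cells[2])))
        rows.append({"set": label, "overlap": a, "log2_odds_ratio": log2_or, "p": float(p)})
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["fdr"] = []
    return out


def mask_jaccard(det_a: DetectionResult, det_b: DetectionResult,
                 threshold: float = DEFAULTS["threshold"]) -> float:
    """Jaccard overlap of the two methods' masked (undetected) probe sets.

    Two empty masks agree perfectly and score 1.0.
    """
    mask_a = set(det_a.p.index[det_a.p >= threshold])
    mask_b = set(det_b.p.index[det_b.p >= threshold])
    union = mask_a | mask_b
    if not union:
        return 1.0
    return len(mask_a & mask_b) / len(union)
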