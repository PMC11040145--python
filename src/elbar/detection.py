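"""Per-probe detection p-values: ELBAR and two baseline callers.

A detection p-value asks: how likely is a signal at least this strong under
a background-only null?  The three callers differ only in how they build
that null:

* ELBAR (:func:`elbar_detect`) — empirical null from probes sitting in the
  background-dominated intensity bins identified via the beta-value
  envelope, plus negative controls.
* pOOBAH (:func:`poobah_detect`) — empirical null from Infinium-I
  out-of-band readings, per colour channel.
* negative-control normal model (:func:`negctl_detect`) — parametric
  normal null fitted to negative-control intensities per channel, in the
  style of minfi's detectionP.

All empirical p-values go through :func:`ecdf_pvalue`, an add-one ECDF
upper-tail probability, so p is always in (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .defaults import DEFAULTS
from .envelope import (
    BackgroundPool,
    bin_by_intensity,
    build_background_pool,
    envelope_quantiles,
    find_background_bins,
    record_betas,
)
from .sigset import SignalSet, compute_betas, total_intensities

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionResult",
    "MaskedBetas",
    "ecdf_pvalue",
    "elbar_detect",
    "poobah_detect",
    "negctl_detect",
    "apply_mask",
]

_TINY_P = 1e-300  # keeps parametric tail probabilities strictly positive


@dataclass
class DetectionResult:
    """Detection p-values for one sample under one method.

    ``p`` is a Series over probe ids with values in (0, 1]; ``params``
    records everything needed to reproduce the run; ``background_summary``
    describes the null (pool size, max, provenance) where applicable.
    """

    method: str
    p: pd.Series
    params: dict = field(default_factory=dict)
    array_wide_failure: bool = False
    background_summary: dict = field(default_factory=dict)


@dataclass
class MaskedBetas:
    """Beta vector with undetected probes (p >= threshold) set to NaN."""

    betas: pd.Series
    threshold: float
    n_masked: int


def ecdf_pvalue(pool: np.ndarray | BackgroundPool, s) -> np.ndarray | float:
    """Add-one empirical upper-tail probability of ``s`` under ``pool``.

    p = (1 + #{b in pool : b >= s}) / (|pool| + 1).  Strictly positive,
    at most 1, non-increasing in s.  ``s`` may be a scalar or array.
    """
    values = pool.values if isinstance(pool, BackgroundPool) else np.asarray(pool, dtype=float)
    if len(values) == 0:
        raise ValueError("empty background pool")
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(s_arr < 0):
        raise ValueError("observed intensity must be >= 0")
    srt = np.sort(values)
    n = len(srt)
    count_ge = n - np.searchsorted(srt, s_arr, side="left")
    p = (1.0 + count_ge) / (n + 1.0)
    return float(p[0]) if np.isscalar(s) or np.ndim(s) == 0 else p


def elbar_detect(
    sigset: SignalSet,
    nbins: int = DEFAULTS["nbins"],
    min_per_bin: int = DEFAULTS["min_per_bin"],
    tau: float = DEFAULTS["tau"],
    q_low_level: float = DEFAULTS["q_low_level"],
    q_high_level: float = DEFAULTS["q_high_level"],
    include_oob: bool = DEFAULTS["include_oob"],
    include_controls: bool = DEFAULTS["include_controls"],
    oob_in_binning: bool = DEFAULTS["oob_in_binning"],
    pool_beta_window: bool = DEFAULTS["pool_beta_window"],
    mode: str = DEFAULTS["mode"],
) -> DetectionResult:
    """ELBAR detection calling.

    Pipeline: pool in-band (and, by default, out-of-band) records; bin them
    by log2 total intensity; compute the per-bin beta envelope; walk up from
    the lowest bin to the first bin whose envelope deviates (onset of real
    signal); treat the probes below it as background and score every probe's
    max(M, U) against that empirical null.

    With ``pool_beta_window`` (default) the null is built only from
    background-bin readings whose beta lies within the lowest bin's
    envelope band — intermediate-methylation readings, the hallmark of
    pure background.  This keeps weak true signal (polarized beta at low
    intensity) out of the null, maximizing sensitivity; it makes the
    null slightly liberal because the extreme-beta background tail is
    trimmed along with it.

    ``mode='ecdf'`` gives a graded add-one ECDF p-value; ``mode='maxbg'``
    implements the hard-threshold reading in which any signal exceeding the
    largest background value is detected (p = 1/(pool+1)) and anything else
    is not (p = 1).

    If no bin deviates the sample is flagged as an array-wide failure;
    p-values are still returned, computed against the all-bin pool, because
    such samples remain legitimate (if empty) data points.
    """
    if mode not in ("ecdf", "maxbg"):
        raise ValueError(f"unknown mode {mode!r}")
    records = total_intensities(sigset, include_oob=oob_in_binning)
    bins = bin_by_intensity(records, nbins=nbins, min_per_bin=min_per_bin)
    betas = record_betas(sigset, bins.records)
    env = envelope_quantiles(betas, bins, q_low_level, q_high_level)
    call = find_background_bins(env, tau=tau)
    beta_band = None
    if pool_beta_window:
        ref_bin = env.index[0]
        beta_band = (float(env.loc[ref_bin, "q_low"]), float(env.loc[ref_bin, "q_high"]))
    pool = build_background_pool(
        sigset, bins, call,
        include_oob=include_oob, include_controls=include_controls,
        betas=betas, beta_band=beta_band,
    )
    m = sigset.probes["M"].to_numpy(dtype=float)
    u = sigset.probes["U"].to_numpy(dtype=float)
    s = np.maximum(m, u)
    if mode == "ecdf":
        p = ecdf_pvalue(pool, s)
    else:
        p_min = 1.0 / (pool.size + 1.0)
        p = np.where(s > pool.max, p_min, 1.0)
    params = {
        "method": "ELBAR",
        "nbins": nbins,
        "min_per_bin": min_per_bin,
        "tau": tau,
        "q_low_level": q_low_level,
        "q_high_level": q_high_level,
        "include_oob": include_oob,
        "include_controls": include_controls,
        "oob_in_binning": oob_in_binning,
        "pool_beta_window": pool_beta_window,
        "beta_band": beta_band,
        "mode": mode,
        "first_deviating_bin": call.first_deviating_bin,
        "n_background_bins": len(call.background_bins),
    }
    return DetectionResult(
        method="ELBAR",
        p=pd.Series(np.asarray(p), index=sigset.probes.index, name="p"),
        params=params,
        array_wide_failure=call.array_wide_failure,
        background_summary={
            "pool_size": pool.size,
            "pool_max": pool.max,
            "provenance": dict(pool.provenance),
        },
    )


def poobah_detect(sigset: SignalSet) -> DetectionResult:
    """Detection p-values from the out-of-band ECDF, per colour channel.

    The null for each channel is the set of all out-of-band intensities
    read in that channel (the OOB reads of Infinium-I probes designed for
    the opposite channel).  An Infinium-I probe is scored on its in-band
    channel with statistic max(M, U); an Infinium-II probe is scored in
    both channels (M in green, U in red) and takes the smaller p-value —
    detected if either allele clears its channel's background.
    """
    p = sigset.probes
    design = p["design"].to_numpy()
    grn_probes = design == "I_GRN"
    red_probes = design == "I_RED"
    if not (grn_probes.any() and red_probes.any()):
        raise ValueError("pOOBAH requires Infinium-I out-of-band signals in both channels")
    # OOB reads of I_RED probes happen in green, and vice versa
    oob_of = lambda mask: np.concatenate(
        [
            p.loc[mask, "oob_M"].to_numpy(dtype=float),
            p.loc[mask, "oob_U"].to_numpy(dtype=float),
        ]
    )
    pool_grn = oob_of(red_probes)
    pool_red = oob_of(grn_probes)
    m = p["M"].to_numpy(dtype=float)
    u = p["U"].to_numpy(dtype=float)
    s_max = np.maximum(m, u)
    pvals = np.ones(len(p))
    pvals[grn_probes] = ecdf_pvalue(pool_grn, s_max[grn_probes])
    pvals[red_probes] = ecdf_pvalue(pool_red, s_max[red_probes])
    two = design == "II"
    if two.any():
        p_g = ecdf_pvalue(pool_grn, m[two])
        p_r = ecdf_pvalue(pool_red, u[two])
        pvals[two] = np.minimum(p_g, p_r)
    return DetectionResult(
        method="POOBAH",
        p=pd.Series(pvals, index=p.index, name="p"),
        params={"method": "POOBAH"},
        background_summary={
            "pool_size": len(pool_grn) + len(pool_red),
            "pool_max": float(max(pool_grn.max(), pool_red.max())),
            "provenance": {"oob_grn": len(pool_grn), "oob_red": len(pool_red)},
        },
    )


def negctl_detect(sigset: SignalSet) -> DetectionResult:
    """Normal-model detection against negative controls.

    Fits a per-channel normal to the negative-control intensities and
    scores each probe's total M + U against the sum of the two channel
    nulls it reads from (means add; variances add).  The p-value is the
    upper-tail normal probability.
    """
    stats_by_ch = {}
    for ch in ("GRN", "RED"):
        vals = sigset.control_intensities(ch)
        if len(vals) < 2:
            raise ValueError(f"need >= 2 negative controls in channel {ch}")
        stats_by_ch[ch] = (float(np.mean(vals)), float(np.var(vals, ddof=1)))
    p = sigset.probes
    ch_pairs = {
        "II": ("GRN", "RED"),
        "I_GRN": ("GRN", "GRN"),
        "I_RED": ("RED", "RED"),
    }
    mu = np.empty(len(p))
    var = np.empty(len(p))
    design = p["design"].to_numpy()
    for d, (cm, cu) in ch_pairs.items():
        sel = design == d
        mu[sel] = stats_by_ch[cm][0] + stats_by_ch[cu][0]
        var[sel] = stats_by_ch[cm][1] + stats_by_ch[cu][1]
    total = p["M"].to_numpy(dtype=float) + p["U"].to_numpy(dtype=float)
    pvals = stats.norm.sf(total, loc=mu, scale=np.sqrt(var))
    pvals = np.clip(pvals, _TINY_P, 1.0)
    return DetectionResult(
        method="NEGCTL",
        p=pd.Series(pvals, index=p.index, name="p"),
        params={
            "method": "NEGCTL",
            "mu_grn": stats_by_ch["GRN"][0],
            "mu_red": stats_by_ch["RED"][0],
            "var_grn": stats_by_ch["GRN"][1],
            "var_red": stats_by_ch["RED"][1],
        },
        background_summary={"pool_size": len(sigset.neg_controls)},
    )


def apply_mask(
    betas: pd.Series, det: DetectionResult, threshold: float = DEFAULTS["threshold"]
) -> MaskedBetas:
    """Mask betas of probes that fail detection (p >= threshold)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    missing = betas.index.difference(det.p.index)
    if len(missing):
        raise ValueError(f"probes missing from detection result: {list(missing[:5])}")
    p = det.p.reindex(betas.index)
    mask = (p >= threshold).to_numpy()
    out = betas.copy()
    out[mask] = np.nan
    return MaskedBetas(betas=out, threshold=threshold, n_masked=int(mask.sum()))


def detect(sigset: SignalSet, method: str = "elbar", **kwargs) -> DetectionResult:
    """Dispatch by method name ('elbar', 'poobah', 'negctl')."""
    method = method.lower()
    if method == "elbar":
        return elbar_detect(sigset, **kwargs)
    if method == "poobah":
        return poobah_detect(sigset)
    if method == "negctl":
        return negctl_detect(sigset)
    raise ValueError(f"unknown detection method {method!r}")


def masked_betas_for(sigset: SignalSet, det: DetectionResult,
                     threshold: float = DEFAULTS["threshold"]) -> MaskedBetas:
    """Convenience: compute betas from the signals, then mask by detection."""
    return apply_mask(compute_betas(sigset), det, threshold=threshold)
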