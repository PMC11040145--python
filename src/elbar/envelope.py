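"""Beta-value envelope background modelling.

The central empirical fact this module exploits: a probe whose fluorescence
is pure background reads roughly equal M and U, so its beta value
``M/(M+U)`` concentrates around 0.5; as true signal grows, betas spread out
towards 0 and 1.  Plotting the per-intensity-bin beta quantile band (the
*beta-value envelope*) against total intensity therefore separates a
background-dominated low-intensity regime (envelope matching the lowest
bin) from a signal-bearing regime (envelope widening).  The background pool
assembled from the background-regime probes, optionally augmented with
negative-control readings, is the empirical null used for detection
p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sigset import SignalSet, TYPE_I_DESIGNS, total_intensities

logger = logging.getLogger(__name__)

__all__ = [
    "BinAssignment",
    "BackgroundCall",
    "BackgroundPool",
    "bin_by_intensity",
    "record_betas",
    "envelope_quantiles",
    "find_background_bins",
    "build_background_pool",
    "theoretical_envelope",
]


@dataclass
class BinAssignment:
    """Result of intensity binning.

    ``records`` is the input record table (columns ``source_id``, ``total``,
    ``is_oob``) with an added 1-based ``bin_index`` column; ``bin_edges``
    are the K+1 ascending log2(total+1) boundaries of the K retained bins.
    """

    records: pd.DataFrame
    bin_edges: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def bin_counts(self) -> pd.Series:
        return self.records["bin_index"].value_counts().sort_index()


@dataclass
class BackgroundCall:
    """Which intensity bins look like pure background.

    ``background_bins`` is a contiguous run starting at bin 1.  When no bin
    deviates from bin 1 the whole array is indistinguishable from
    background and ``array_wide_failure`` is set.
    """

    background_bins: tuple[int, ...]
    first_deviating_bin: int | None
    array_wide_failure: bool
    tau: float


@dataclass
class BackgroundPool:
    """Empirical null sample of background-level fluorescence.

    ``values`` holds one max(M, U) statistic per contributing probe record
    (matching the detection statistic) plus raw negative-control
    intensities; ``provenance`` counts values by origin.
    """

    values: np.ndarray
    provenance: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.values)

    @property
    def max(self) -> float:
        return float(np.max(self.values))


def bin_by_intensity(
    records: pd.DataFrame, nbins: int = 20, min_per_bin: int = 100
) -> BinAssignment:
    """Bin signal records by log2-transformed total intensity.

    Equal-width bins are laid over ``log2(total + 1)`` between the observed
    minimum and maximum of the positive totals; records with ``total == 0``
    fall into bin 1.  Bins holding fewer than ``min_per_bin`` records are
    merged into their lower-intensity neighbour (bin 1 merges upward), so
    every retained bin is adequately populated for quantile estimation.
    """
    n = len(records)
    if n < max(min_per_bin, 2):
        raise ValueError("insufficient probes")
    totals = records["total"].to_numpy(dtype=float)
    log_t = np.log2(totals + 1.0)
    pos = log_t[totals > 0]
    if len(pos) == 0:
        raise ValueError("insufficient probes")
    lo, hi = float(pos.min()), float(pos.max())
    if hi <= lo:
        edges = np.array([lo, hi if hi > lo else lo + 1e-9])
        idx = np.ones(n, dtype=int)
        out = records.copy()
        out["bin_index"] = idx
        return BinAssignment(records=out, bin_edges=edges)
    nbins = int(min(nbins, max(1, len(pos))))
    edges = np.linspace(lo, hi, nbins + 1)
    # right-open bins except the last; zero totals forced into bin 1
    idx = np.clip(np.searchsorted(edges, log_t, side="right"), 1, nbins)
    idx[totals == 0] = 1

    counts = np.bincount(idx, minlength=nbins + 1)[1:]
    edges = list(edges)
    counts = list(counts)
    while len(counts) > 1 and min(counts) < min_per_bin:
        k = next(i for i, c in enumerate(counts) if c < min_per_bin)
        if k == 0:
            # bin 1 merges upward to keep the lowest-intensity reference
            counts[1] += counts[0]
            del counts[0]
            del edges[1]
            idx = np.where(idx <= 2, 1, idx - 1)
        else:
            counts[k - 1] += counts[k]
            del counts[k]
            del edges[k]
            idx = np.where(idx > k, idx - 1, idx)
    out = records.copy()
    out["bin_index"] = idx
    return BinAssignment(records=out, bin_edges=np.asarray(edges, dtype=float))


def record_betas(sigset: SignalSet, records: pd.DataFrame) -> np.ndarray:
    """Beta value per binning record, aligned positionally with ``records``.

    In-band records use M/(M+U); out-of-band records (Infinium-I only) use
    oob_M/(oob_M+oob_U), since an OOB read pair is a paired allele reading
    like any other.  NaN where the record total is zero.
    """
    p = sigset.probes
    out = np.full(len(records), np.nan)
    src = records["source_id"].to_numpy()
    is_oob = records["is_oob"].to_numpy(dtype=bool)
    m_in = p["M"].reindex(src).to_numpy(dtype=float)
    u_in = p["U"].reindex(src).to_numpy(dtype=float)
    m_ob = p["oob_M"].reindex(src).to_numpy(dtype=float)
    u_ob = p["oob_U"].reindex(src).to_numpy(dtype=float)
    m = np.where(is_oob, m_ob, m_in)
    u = np.where(is_oob, u_ob, u_in)
    tot = m + u
    good = np.isfinite(tot) & (tot > 0)
    out[good] = m[good] / tot[good]
    return out


def envelope_quantiles(
    betas: np.ndarray,
    bins: BinAssignment,
    q_low_level: float = 0.05,
    q_high_level: float = 0.95,
) -> pd.DataFrame:
    """Per-bin beta-value envelope: lower/upper quantiles of the bin's betas.

    Quantiles use linear interpolation between order statistics (position =
    level x (n - 1)); undefined betas are excluded from a bin's sample.
    Bins with fewer than two defined betas are dropped with a warning.

    Returns a frame indexed by ``bin_index`` with columns ``q_low``,
    ``q_high``, ``n`` and ``median_log2_total``.
    """
    if not 0 <= q_low_level <= q_high_level <= 1:
        raise ValueError("quantile levels must satisfy 0 <= low <= high <= 1")
    betas = np.asarray(betas, dtype=float)
    rec = bins.records
    if len(betas) != len(rec):
        raise ValueError("betas must align with the binned records")
    rows = []
    log_t = np.log2(rec["total"].to_numpy(dtype=float) + 1.0)
    bin_idx = rec["bin_index"].to_numpy()
    for b in range(1, bins.n_bins + 1):
        sel = bin_idx == b
        vals = betas[sel]
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            logger.warning("bin %d has %d defined betas; excluded from envelope", b, len(vals))
            continue
        rows.append(
            {
                "bin_index": b,
                "q_low": float(np.quantile(vals, q_low_level)),
                "q_high": float(np.quantile(vals, q_high_level)),
                "n": int(sel.sum()),
                "median_log2_total": float(np.median(log_t[sel])),
            }
        )
    return pd.DataFrame(rows).set_index("bin_index")


def find_background_bins(env: pd.DataFrame, tau: float = 0.1) -> BackgroundCall:
    """Identify the background-dominated low-intensity bins.

    Scanning upward from the lowest-intensity bin, the first bin whose
    envelope deviates from bin 1 by more than ``tau`` (in either quantile)
    marks the onset of real signal; everything below it is background.  If
    no bin deviates, nothing on the array is distinguishable from
    background and the call is an array-wide failure.
    """
    if len(env) < 1:
        raise ValueError("envelope has no usable bins")
    bins = list(env.index)
    q_low = env["q_low"].to_numpy(dtype=float)
    q_high = env["q_high"].to_numpy(dtype=float)
    first_dev = None
    for k in range(1, len(bins)):
        dev = max(abs(q_low[k] - q_low[0]), abs(q_high[k] - q_high[0]))
        if dev > tau:
            first_dev = bins[k]
            break
    if first_dev is None:
        return BackgroundCall(
            background_bins=tuple(bins),
            first_deviating_bin=None,
            array_wide_failure=True,
            tau=tau,
        )
    return BackgroundCall(
        background_bins=tuple(b for b in bins if b < first_dev),
        first_deviating_bin=first_dev,
        array_wide_failure=False,
        tau=tau,
    )


def build_background_pool(
    sigset: SignalSet,
    bins: BinAssignment,
    call: BackgroundCall,
    include_oob: bool = False,
    include_controls: bool = True,
    betas: np.ndarray | None = None,
    beta_band: tuple[float, float] | None = None,
) -> BackgroundPool:
    """Assemble the empirical background pool.

    Every in-band record falling in a background bin contributes its
    max(M, U) — the strongest reading background produced on that probe,
    mirroring the detection statistic so that the null and the statistic
    are drawn from the same distribution.  Optionally all Infinium-I
    out-of-band read pairs contribute max(oob_M, oob_U), and negative
    controls contribute their raw intensities.

    When ``beta_band`` is given (with record-aligned ``betas``), only
    records whose beta lies inside the band contribute: the background
    model is then built from intermediate-methylation readings only,
    which keeps low-intensity true signal (polarized betas) out of the
    null at the price of trimming the extreme-beta background tail.
    """
    p = sigset.probes
    rec = bins.records
    bg = set(call.background_bins)
    keep = ~rec["is_oob"].to_numpy(dtype=bool) & rec["bin_index"].isin(bg).to_numpy()
    if beta_band is not None:
        if betas is None or len(betas) != len(rec):
            raise ValueError("beta_band requires record-aligned betas")
        lo, hi = beta_band
        b = np.asarray(betas, dtype=float)
        keep &= np.isfinite(b) & (b >= lo) & (b <= hi)
    in_band = rec[keep]
    ids = in_band["source_id"].to_numpy()
    m = p["M"].reindex(ids).to_numpy(dtype=float)
    u = p["U"].reindex(ids).to_numpy(dtype=float)
    parts = [np.maximum(m, u)]
    prov = {"in_band_max": len(ids)}
    if include_oob:
        one = p[p["design"].isin(TYPE_I_DESIGNS)]
        oob = np.maximum(
            one["oob_M"].to_numpy(dtype=float), one["oob_U"].to_numpy(dtype=float)
        )
        parts.append(oob)
        prov["oob_max"] = len(oob)
    else:
        prov["oob_max"] = 0
    if include_controls:
        ctl = sigset.control_intensities()
        parts.append(ctl)
        prov["neg_controls"] = len(ctl)
    else:
        prov["neg_controls"] = 0
    values = np.concatenate(parts) if parts else np.array([])
    if len(values) == 0:
        raise ValueError("no background evidence")
    return BackgroundPool(values=values, provenance=prov)


def theoretical_envelope(
    b_grn: float, b_red: float, totals: np.ndarray
) -> pd.DataFrame:
    """Closed-form envelope curves implied by fixed per-channel backgrounds.

    With a background level B on the channel and total intensity T, the
    most extreme betas attainable are B/T (all signal unmethylated) and
    1 - B/T (all methylated); the curves pinch to 0.5 at T = 2B, below
    which every reading is background-dominated.
    """
    if b_grn <= 0 or b_red <= 0:
        raise ValueError("background levels must be positive")
    totals = np.asarray(totals, dtype=float)
    bad = totals <= 0
    if bad.any():
        logger.warning("excluding %d non-positive totals from envelope grid", int(bad.sum()))
        totals = totals[~bad]
    out = {"total": totals}
    for name, b in (("grn", b_grn), ("red", b_red)):
        out[f"{name}_lower"] = np.minimum(b / totals, 0.5)
        out[f"{name}_upper"] = np.maximum(1.0 - b / totals, 0.5)
    return pd.DataFrame(out)
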