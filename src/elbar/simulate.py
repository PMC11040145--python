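"""Synthetic BeadChip signal generator for the low-input regime.

The generator reproduces, with known ground truth, the signal phenomena
that drive detection calling on real low-input arrays:

* **Dropout.** Each probe captures a Poisson number of template copies
  with mean proportional to input amount, locus copy number (mitochondria
  and high-copy transposable elements rarely drop out) and probe C-content
  (GC-rich probes capture better).  A probe with zero captured copies
  reads pure background on both channels and its beta collapses towards
  0.5 — the background-dominated reading ELBAR is designed to mask.
* **Allelic betas.** The population methylation fraction beta_true is
  realized over 2 x n_cells alleles, so few-cell samples produce
  dichotomized betas (single cells read 0, 0.5 or 1).
* **Amplification.** A captured template is whole-genome preamplified, so
  even one captured copy yields a clearly foreground intensity
  (``signal_per_copy``), with lognormal amplification noise.
* **Out-of-band reads.** The allele-flipped bead of an Infinium-I probe
  still hybridizes template (its own locus and off-target amplified DNA),
  so whenever any template is present OOB readings are background-shaped
  but scale-inflated relative to negative controls — the reason an
  OOB-based null over-masks low-input data while the scrambled-sequence
  negative controls stay at optical background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sigset import Manifest, SignalSet

__all__ = [
    "SimConfig",
    "simulate_manifest",
    "simulate_sample",
    "simulate_titration",
    "simulate_two_regime_records",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.  Defaults emulate a saturating-input sample.

    ``input_scale`` is the fraction of a saturating DNA input (1.0 ≈ the
    250-ng regime, 0 = no template at all); ``capture_rate`` is the mean
    number of captured template copies per single-copy probe at
    input_scale 1.  ``signal_per_copy`` is the post-amplification
    fluorescence contributed by one captured copy, deliberately large
    relative to the per-channel background mean because preamplification
    brings any captured locus to near-saturation.
    """

    n_probes: int = 20_000
    frac_type2: float = 0.7
    n_cells: int = 5
    input_scale: float = 1.0
    capture_rate: float = 25.0
    signal_per_copy: float = 2000.0
    gc_effect: float = 0.05
    copy_multiplier: dict = field(
        default_factory=lambda: {"SINGLE": 1.0, "TE_HIGH": 10.0, "MITO": 200.0}
    )
    bg_mean_grn: float = 250.0
    bg_mean_red: float = 250.0
    bg_shape: float = 4.0
    oob_offtarget: float = 1.0
    amp_noise_sd: float = 0.3
    frac_intermediate: float = 0.2
    n_neg_controls: int = 400
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_type2", "frac_intermediate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.input_scale < 0:
            raise ValueError("input_scale must be >= 0")
        for name in ("capture_rate", "signal_per_copy", "bg_mean_grn",
                     "bg_mean_red", "bg_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


_COPY_CLASS_PROBS = {"SINGLE": 0.94, "TE_HIGH": 0.05, "MITO": 0.01}


def simulate_manifest(config: SimConfig) -> Manifest:
    """Generate a probe manifest: designs, C-counts, copy classes, sets.

    Type-I probes split evenly between channels (deterministic rounding).
    ``n_C`` is uniform on {5..25}.  Curated sets: ``GC_rich`` is exactly
    the top quartile by n_C (ceil(0.25 n) probes), ``CpG_island`` is a
    random set with membership probability rising in n_C, ``PGCMeth`` a
    random 5%, and ``TE`` all TE_HIGH probes.
    """
    n = config.n_probes
    if n < 10:
        raise ValueError("n_probes must be >= 10")
    rng = np.random.default_rng([config.seed, 101])
    n2 = round(config.frac_type2 * n)
    n1 = n - n2
    n_grn = n1 // 2 + (n1 % 2)
    designs = np.array(["II"] * n2 + ["I_GRN"] * n_grn + ["I_RED"] * (n1 - n_grn))
    rng.shuffle(designs)
    n_c = rng.integers(5, 26, size=n)
    classes = rng.choice(
        list(_COPY_CLASS_PROBS), size=n, p=list(_COPY_CLASS_PROBS.values())
    )
    ids = np.array([f"cg{i:08d}" for i in range(n)])

    k_gc = math.ceil(0.25 * n)
    order = np.lexsort((np.arange(n), -n_c))  # by n_C desc, stable
    gc_rich = np.zeros(n, dtype=bool)
    gc_rich[order[:k_gc]] = True
    island = rng.random(n) < (0.02 + 0.012 * (n_c - 5))
    pgcmeth = rng.random(n) < 0.05
    te = classes == "TE_HIGH"

    sets_col = []
    for i in range(n):
        labels = []
        if gc_rich[i]:
            labels.append("GC_rich")
        if island[i]:
            labels.append("CpG_island")
        if pgcmeth[i]:
            labels.append("PGCMeth")
        if te[i]:
            labels.append("TE")
        sets_col.append(",".join(labels))

    table = pd.DataFrame(
        {
            "design": designs,
            "n_C": n_c.astype(int),
            "copy_class": classes,
            "probe_sets": sets_col,
        },
        index=pd.Index(ids, name="probe_id"),
    )
    return Manifest(table)


def _beta_true(config: SimConfig, n: int) -> np.ndarray:
    """Population methylation fractions; keyed by config.seed only so every
    sample simulated under the same config shares the same truth."""
    rng = np.random.default_rng([config.seed, 202])
    r = rng.random(n)
    inter = rng.random(n)
    fi = config.frac_intermediate
    lo = (1 - fi) / 2
    return np.where(r < lo, 0.0, np.where(r < 1 - fi, 1.0, inter))


def simulate_sample(
    manifest: Manifest, config: SimConfig, sample_key: int = 0, sample_id: str | None = None
) -> tuple[SignalSet, pd.DataFrame]:
    """Simulate one sample; returns the SignalSet and its ground truth.

    The truth table has columns ``beta_true``, ``beta_realized``,
    ``captured_copies`` and ``background_only`` indexed by probe id.
    """
    t = manifest.table
    n = len(t)
    beta_true = _beta_true(config, n)
    rng = np.random.default_rng([config.seed, 303, sample_key])

    alleles = 2 * config.n_cells
    k = rng.binomial(alleles, beta_true)
    beta_realized = k / alleles

    n_c = t["n_C"].to_numpy(dtype=float)
    gc_factor = np.clip(1.0 + config.gc_effect * (n_c - n_c.mean()), 0.01, None)
    mult = t["copy_class"].map(config.copy_multiplier).to_numpy(dtype=float)
    lam = config.capture_rate * config.input_scale * mult * gc_factor
    captured = rng.poisson(lam)

    amp = rng.lognormal(0.0, config.amp_noise_sd, size=n)
    fg = captured * config.signal_per_copy * amp
    fg_m = fg * beta_realized
    fg_u = fg * (1.0 - beta_realized)

    design = t["design"].to_numpy()
    bg_mean = {"GRN": config.bg_mean_grn, "RED": config.bg_mean_red}
    ch_m = np.where(design == "I_RED", "RED", "GRN")  # II and I_GRN read M in green
    ch_u = np.where(design == "II", "RED", np.where(design == "I_RED", "RED", "GRN"))
    shape = config.bg_shape

    def bg_draw(channels: np.ndarray) -> np.ndarray:
        scale = np.array([bg_mean[c] for c in channels]) / shape
        return rng.gamma(shape, scale)

    m_sig = fg_m + bg_draw(ch_m)
    u_sig = fg_u + bg_draw(ch_u)

    # OOB reads: background-shaped, scale-inflated when template is present
    is_one = np.isin(design, ("I_GRN", "I_RED"))
    oob_boost = 1.0 + (config.oob_offtarget if config.input_scale > 0 else 0.0)
    oob_m = np.full(n, np.nan)
    oob_u = np.full(n, np.nan)
    opp = np.where(design == "I_GRN", "RED", "GRN")
    oob_scale = np.array([bg_mean[c] for c in opp]) / shape * oob_boost
    oob_m[is_one] = rng.gamma(shape, oob_scale[is_one])
    oob_u[is_one] = rng.gamma(shape, oob_scale[is_one])

    ctl_rows = []
    for ch in ("GRN", "RED"):
        vals = rng.gamma(shape, bg_mean[ch] / shape, size=config.n_neg_controls)
        ctl_rows.append(
            pd.DataFrame(
                {
                    "control_id": [f"NEG_{ch}_{i:04d}" for i in range(config.n_neg_controls)],
                    "channel": ch,
                    "intensity": vals,
                }
            )
        )
    controls = pd.concat(ctl_rows, ignore_index=True)

    probes = pd.DataFrame(
        {"design": design, "M": m_sig, "U": u_sig, "oob_M": oob_m, "oob_U": oob_u},
        index=t.index,
    )
    if sample_id is None:
        sample_id = f"sim_seed{config.seed}_k{sample_key}"
    sigset = SignalSet(sample_id=sample_id, probes=probes, neg_controls=controls)
    truth = pd.DataFrame(
        {
            "beta_true": beta_true,
            "beta_realized": beta_realized,
            "captured_copies": captured,
            "background_only": captured == 0,
        },
        index=t.index,
    )
    return sigset, truth


def simulate_titration(
    manifest: Manifest,
    config: SimConfig,
    input_scales: list[float],
    cells_list: list[int],
) -> list[tuple[SignalSet, pd.DataFrame]]:
    """One sample per (input_scale, n_cells) pair, deterministically seeded.

    All samples share the manifest and beta_true; per-sample randomness is
    keyed by the pair index, so a rerun reproduces identical output.
    """
    if not input_scales or not cells_list:
        raise ValueError("input_scales and cells_list must be non-empty")
    out = []
    key = 0
    for scale in input_scales:
        for cells in cells_list:
            key += 1
            cfg = replace(config, input_scale=scale, n_cells=cells)
            out.append(
                simulate_sample(
                    manifest, cfg, sample_key=key,
                    sample_id=f"sim_scale{scale}_cells{cells}",
                )
            )
    return out


def simulate_two_regime_records(
    n_bg: int,
    n_fg: int,
    onset_log2: float,
    rng: np.random.Generator,
    bg_mean: float = 250.0,
    bg_shape: float = 4.0,
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Construct a two-regime record set with a known foreground onset.

    Background records draw totals from the sum of two per-channel Gamma
    backgrounds and betas from the corresponding background beta law;
    foreground records draw log2 totals uniformly from [onset_log2,
    onset_log2 + 2] with strongly polarized betas.  Returns (records,
    betas, onset_log2) ready for binning and envelope analysis — used for
    onset-recovery checks of the background-bin search.
    """
    bg_m = rng.gamma(bg_shape, bg_mean / bg_shape, size=n_bg)
    bg_u = rng.gamma(bg_shape, bg_mean / bg_shape, size=n_bg)
    bg_tot = bg_m + bg_u
    bg_beta = bg_m / bg_tot
    fg_tot = 2.0 ** rng.uniform(onset_log2, onset_log2 + 2.0, size=n_fg)
    meth = rng.random(n_fg) < 0.5
    fg_beta = np.where(meth, rng.beta(95, 5, size=n_fg), rng.beta(5, 95, size=n_fg))
    records = pd.DataFrame(
        {
            "source_id": [f"r{i}" for i in range(n_bg + n_fg)],
            "total": np.concatenate([bg_tot, fg_tot]),
            "is_oob": False,
        }
    )
    betas = np.concatenate([bg_beta, fg_beta])
    return records, betas, onset_log2
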