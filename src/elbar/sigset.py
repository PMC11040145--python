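"""Signal data model and plain-text I/O for Infinium BeadChip probe signals.

An Infinium methylation array reads, for every targeted CpG, two fluorescence
intensities: M (methylated allele) and U (unmethylated allele).  Infinium-I
probes read both alleles in a single colour channel (green or red, the
*in-band* channel); the opposite channel still produces readings, the
*out-of-band* (OOB) signals, which carry no target signal and therefore
measure pure background.  Infinium-II probes read the methylated allele in
green and the unmethylated allele in red and have no out-of-band reads.

This module defines the in-memory containers (:class:`SignalSet`,
:class:`Manifest`), the tab-separated on-disk dialect, and the two most basic
derived quantities: beta values ``M / (M + U)`` and total intensities
``M + U``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DESIGNS",
    "TYPE_I_DESIGNS",
    "SignalSet",
    "Manifest",
    "SignalFormatError",
    "SignalValidationError",
    "read_signal_table",
    "write_signal_table",
    "read_controls_table",
    "write_controls_table",
    "read_manifest",
    "write_manifest",
    "compute_betas",
    "total_intensities",
]

DESIGNS = ("I_GRN", "I_RED", "II")
TYPE_I_DESIGNS = ("I_GRN", "I_RED")
CHANNELS = ("GRN", "RED")
COPY_CLASSES = ("SINGLE", "MITO", "TE_HIGH")

_SIGNAL_COLUMNS = ["probe_id", "design", "M", "U", "oob_M", "oob_U"]
_CONTROL_COLUMNS = ["control_id", "channel", "intensity"]
_MANIFEST_COLUMNS = ["probe_id", "design", "n_C", "copy_class", "probe_sets"]


class SignalFormatError(ValueError):
    """A file does not conform to the signal/manifest TSV dialect."""


class SignalValidationError(ValueError):
    """Parsed values violate an invariant (negative intensity, missing OOB...)."""


@dataclass
class SignalSet:
    """Raw probe-level fluorescence readings for one sample.

    Parameters
    ----------
    sample_id
        Free-form sample label.
    probes
        One row per probe, columns ``design`` (``I_GRN``/``I_RED``/``II``),
        ``M``, ``U`` and, for Infinium-I probes only, ``oob_M``/``oob_U``
        (NaN for type II).  Indexed by probe id.
    neg_controls
        Negative-control readings: columns ``control_id``, ``channel``
        (``GRN``/``RED``) and ``intensity``.  May be empty.
    """

    sample_id: str
    probes: pd.DataFrame
    neg_controls: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_CONTROL_COLUMNS)
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p = self.probes
        if len(p) == 0:
            raise SignalValidationError("SignalSet requires at least one probe")
        if not p.index.is_unique:
            dup = p.index[p.index.duplicated()][0]
            raise SignalValidationError(f"duplicate probe_id {dup!r}")
        bad_design = set(p["design"]) - set(DESIGNS)
        if bad_design:
            raise SignalValidationError(f"unknown design value(s): {sorted(bad_design)}")
        for col in ("M", "U"):
            v = p[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(v)):
                raise SignalValidationError(f"non-finite value in column {col}")
            if np.any(v < 0):
                raise SignalValidationError(f"negative intensity in column {col}")
        is_one = p["design"].isin(TYPE_I_DESIGNS).to_numpy()
        for col in ("oob_M", "oob_U"):
            v = p[col].to_numpy(dtype=float)
            if np.any(is_one & ~np.isfinite(v)):
                row = p.index[is_one & ~np.isfinite(v)][0]
                raise SignalValidationError(
                    f"Infinium-I probe {row!r} is missing out-of-band column {col}"
                )
            if np.any(~is_one & np.isfinite(v)):
                row = p.index[~is_one & np.isfinite(v)][0]
                raise SignalValidationError(
                    f"type-II probe {row!r} must not carry out-of-band column {col}"
                )
            if np.any(np.isfinite(v) & (v < 0)):
                raise SignalValidationError(f"negative intensity in column {col}")
        c = self.neg_controls
        if len(c):
            bad_ch = set(c["channel"]) - set(CHANNELS)
            if bad_ch:
                raise SignalValidationError(f"unknown control channel(s): {sorted(bad_ch)}")
            v = c["intensity"].to_numpy(dtype=float)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise SignalValidationError("control intensities must be finite and >= 0")

    @property
    def probe_ids(self) -> pd.Index:
        return self.probes.index

    def control_intensities(self, channel: str | None = None) -> np.ndarray:
        c = self.neg_controls
        if channel is not None:
            c = c[c["channel"] == channel]
        return c["intensity"].to_numpy(dtype=float)


@dataclass
class Manifest:
    """Static per-probe annotation.

    ``table`` is indexed by probe id with columns ``design``, ``n_C`` (count
    of C bases in the probe sequence, a GC proxy on bisulfite-converted
    DNA), ``copy_class`` (``SINGLE``/``MITO``/``TE_HIGH``) and ``probe_sets``
    (comma-separated curated set labels, possibly empty).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if not t.index.is_unique:
            raise SignalValidationError("duplicate probe_id in manifest")
        bad = set(t["copy_class"]) - set(COPY_CLASSES)
        if bad:
            raise SignalValidationError(f"unknown copy_class value(s): {sorted(bad)}")
        if (t["n_C"].to_numpy(dtype=float) < 0).any():
            raise SignalValidationError("n_C must be >= 0")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def set_universe(self) -> list[str]:
        """All probe-set labels occurring in the manifest, sorted."""
        labels: set[str] = set()
        for s in self.table["probe_sets"]:
            if s:
                labels.update(s.split(","))
        return sorted(labels)

    def probes_in_set(self, label: str) -> pd.Index:
        mask = self.table["probe_sets"].map(
            lambda s: label in s.split(",") if s else False
        )
        return self.table.index[mask]

    def lookup(self, probe_ids: Iterable[str]) -> pd.DataFrame:
        ids = pd.Index(probe_ids)
        missing = ids.difference(self.table.index)
        if len(missing):
            raise KeyError(f"probe(s) absent from manifest: {list(missing[:5])}")
        return self.table.loc[ids]


def _check_no_tabs(values: Iterable[str], what: str) -> None:
    for v in values:
        if "\t" in str(v):
            raise SignalValidationError(f"{what} {v!r} contains a tab character")


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SignalFormatError(f"{path}: missing required column(s) {missing}")
    return df


def _to_float(df: pd.DataFrame, col: str, path, allow_empty: bool = False) -> np.ndarray:
    raw = df[col].to_numpy()
    out = np.full(len(raw), np.nan)
    for i, s in enumerate(raw):
        s = s.strip()
        if s == "":
            if allow_empty:
                continue
            raise SignalValidationError(f"{path} row {i + 2}: empty value in column {col}")
        try:
            out[i] = float(s)
        except ValueError:
            raise SignalValidationError(
                f"{path} row {i + 2}: non-numeric value {s!r} in column {col}"
            ) from None
        if out[i] < 0:
            raise SignalValidationError(
                f"{path} row {i + 2}: negative intensity in column {col}"
            )
    return out


def read_signal_table(
    path: str | Path,
    controls_path: str | Path | None = None,
    sample_id: str | None = None,
) -> SignalSet:
    """Read a per-sample signal TSV (plus optional companion controls TSV).

    The signal dialect is one header row with columns ``probe_id``,
    ``design``, ``M``, ``U``, ``oob_M``, ``oob_U`` (the OOB cells are empty
    for type-II probes).  Row order is preserved.
    """
    df = _read_tsv(path, _SIGNAL_COLUMNS)
    probes = pd.DataFrame(
        {
            "design": df["design"].to_numpy(),
            "M": _to_float(df, "M", path),
            "U": _to_float(df, "U", path),
            "oob_M": _to_float(df, "oob_M", path, allow_empty=True),
            "oob_U": _to_float(df, "oob_U", path, allow_empty=True),
        },
        index=pd.Index(df["probe_id"], name="probe_id"),
    )
    if controls_path is not None:
        controls = read_controls_table(controls_path)
    else:
        controls = pd.DataFrame(columns=_CONTROL_COLUMNS)
    if sample_id is None:
        sample_id = Path(path).stem
    return SignalSet(sample_id=sample_id, probes=probes, neg_controls=controls)


def read_controls_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, _CONTROL_COLUMNS)
    return pd.DataFrame(
        {
            "control_id": df["control_id"].to_numpy(),
            "channel": df["channel"].to_numpy(),
            "intensity": _to_float(df, "intensity", path),
        }
    )


def _fmt(x: float) -> str:
    if not np.isfinite(x):
        return ""
    return repr(float(x))


def write_signal_table(
    sigset: SignalSet,
    path: str | Path,
    controls_path: str | Path | None = None,
) -> None:
    """Write a SignalSet in the dialect read by :func:`read_signal_table`.

    Floats are written with ``repr`` so a round trip is bit-exact.
    """
    sigset.validate()
    _check_no_tabs(sigset.probes.index, "probe_id")
    p = sigset.probes
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_SIGNAL_COLUMNS) + "\n")
        for pid, row in p.iterrows():
            fh.write(
                "\t".join(
                    [
                        str(pid),
                        row["design"],
                        _fmt(row["M"]),
                        _fmt(row["U"]),
                        _fmt(row["oob_M"]),
                        _fmt(row["oob_U"]),
                    ]
                )
                + "\n"
            )
    if controls_path is not None:
        write_controls_table(sigset.neg_controls, controls_path)


def write_controls_table(controls: pd.DataFrame, path: str | Path) -> None:
    _check_no_tabs(controls["control_id"], "control_id")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_CONTROL_COLUMNS) + "\n")
        for _, row in controls.iterrows():
            fh.write(f"{row['control_id']}\t{row['channel']}\t{_fmt(row['intensity'])}\n")


def read_manifest(path: str | Path) -> Manifest:
    df = _read_tsv(path, _MANIFEST_COLUMNS)
    n_c = pd.to_numeric(df["n_C"], errors="coerce")
    if n_c.isna().any():
        raise SignalValidationError(f"{path}: non-numeric n_C value")
    table = pd.DataFrame(
        {
            "design": df["design"].to_numpy(),
            "n_C": n_c.astype(int).to_numpy(),
            "copy_class": df["copy_class"].to_numpy(),
            "probe_sets": df["probe_sets"].to_numpy(),
        },
        index=pd.Index(df["probe_id"], name="probe_id"),
    )
    return Manifest(table)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    _check_no_tabs(manifest.table.index, "probe_id")
    t = manifest.table
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_MANIFEST_COLUMNS) + "\n")
        for pid, row in t.iterrows():
            fh.write(
                f"{pid}\t{row['design']}\t{int(row['n_C'])}\t"
                f"{row['copy_class']}\t{row['probe_sets']}\n"
            )


def compute_betas(sigset: SignalSet) -> pd.Series:
    """Beta values ``M / (M + U)`` per probe; NaN where ``M + U == 0``.

    No pseudo-count offset is applied: probes reading pure background then
    centre at 0.5, which is exactly the geometry the background envelope
    relies on.  A zero total is a distinct "no reading" state and maps to
    NaN rather than 0.5.
    """
    m = sigset.probes["M"].to_numpy(dtype=float)
    u = sigset.probes["U"].to_numpy(dtype=float)
    tot = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(tot > 0, m / np.where(tot > 0, tot, 1.0), np.nan)
    return pd.Series(beta, index=sigset.probes.index, name="beta")


def total_intensities(sigset: SignalSet, include_oob: bool = False) -> pd.DataFrame:
    """Total signal per source: one in-band M+U record per probe and, when
    ``include_oob``, one additional oob_M+oob_U record per Infinium-I probe.

    Returns a frame with columns ``source_id``, ``total``, ``is_oob``.
    Out-of-band records reuse the probe id as source id but are flagged.
    """
    p = sigset.probes
    records = [
        pd.DataFrame(
            {
                "source_id": p.index,
                "total": p["M"].to_numpy(dtype=float) + p["U"].to_numpy(dtype=float),
                "is_oob": False,
            }
        )
    ]
    if include_oob:
        one = p[p["design"].isin(TYPE_I_DESIGNS)]
        if len(one):
            records.append(
                pd.DataFrame(
                    {
                        "source_id": one.index,
                        "total": one["oob_M"].to_numpy(dtype=float)
                        + one["oob_U"].to_numpy(dtype=float),
                        "is_oob": True,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)
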