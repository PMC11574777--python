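"""Plate readout ingestion, control normalization, and assay QC.

Raw well signals (relative luminescence units from a viability assay) are
normalized to the mean of the plate's untreated negative-control wells,
giving normalized cell viability (NCV): 1 = no effect, 0 = complete kill.
Assay quality is summarized by the Z'-factor and the strictly standardized
mean difference (SSMD) between positive and negative controls; runs with
Z' below the gate threshold are excluded from downstream modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlateReadout",
    "NormalizedResponse",
    "QCMetrics",
    "read_plate",
    "normalize_to_controls",
    "compute_zprime",
    "compute_ssmd",
    "qc_gate",
]

NEGATIVE = "negative_control"
POSITIVE = "positive_control"
DESIGN = "design_row"

#: default exclusion gate on Z' (runs below are excluded; the boundary passes)
ZPRIME_GATE = 0.7


@dataclass(frozen=True)
class PlateReadout:
    """Validated plate data: one record per well.

    ``wells`` has columns ``well`` (id), ``signal`` (raw RLU, >= 0),
    ``role`` (negative_control / positive_control / design_row) and
    ``design_row`` (int index into the design for treated wells, else NA).
    Replicates are wells sharing a design row.
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.wells
        required = {"well", "signal", "role", "design_row"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        if df["well"].duplicated().any():
            dup = df.loc[df["well"].duplicated(), "well"].iloc[0]
            raise ValueError(f"duplicate well id {dup!r}")
        sig = df["signal"].to_numpy(dtype=float)
        if not np.isfinite(sig).all():
            raise ValueError("non-finite signal values in readout")
        if (sig < 0).any():
            bad = df.loc[sig < 0, "well"].iloc[0]
            raise ValueError(f"negative signal in well {bad!r}")
        roles = set(df["role"])
        unknown = roles - {NEGATIVE, POSITIVE, DESIGN}
        if unknown:
            raise ValueError(f"unknown well roles: {sorted(unknown)}")
        if (df["role"] == NEGATIVE).sum() < 2:
            raise ValueError("at least 2 negative-control wells required")
        treated = df[df["role"] == DESIGN]
        if treated["design_row"].isna().any():
            bad = treated.loc[treated["design_row"].isna(), "well"].iloc[0]
            raise ValueError(f"design well {bad!r} lacks a design_row")

    def signals(self, role: str) -> np.ndarray:
        return self.wells.loc[self.wells["role"] == role, "signal"].to_numpy(float)

    @property
    def n_design_rows(self) -> int:
        return self.wells.loc[self.wells["role"] == DESIGN, "design_row"].nunique()


@dataclass(frozen=True)
class NormalizedResponse:
    """Per-design-row NCV (replicate mean) and replicate SD."""

    ncv: pd.Series  # index = design row
    replicate_sd: pd.Series

    @property
    def values(self) -> np.ndarray:
        return self.ncv.to_numpy(float)


@dataclass(frozen=True)
class QCMetrics:
    zprime: float
    ssmd: float
    passed: bool
    threshold: float = ZPRIME_GATE


def read_plate(readout_path: str | Path, layout_path: str | Path) -> PlateReadout:
    """Join a (well, signal) readout table with a (well, role, design_row,
    replicate) layout table into a validated :class:`PlateReadout`."""
    readout = pd.read_csv(readout_path)
    layout = pd.read_csv(layout_path)
    for name, df, cols in (
        ("readout", readout, {"well", "signal"}),
        ("layout", layout, {"well", "role"}),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"{name} file missing columns: {sorted(missing)}")
    if "design_row" not in layout.columns:
        layout["design_row"] = pd.NA
    unmapped = set(readout["well"]) - set(layout["well"])
    if unmapped:
        raise ValueError(f"layout has no entry for wells: {sorted(unmapped)[:5]}")
    merged = readout.merge(
        layout[["well", "role", "design_row"]], on="well", how="left"
    )
    merged["design_row"] = pd.to_numeric(merged["design_row"], errors="coerce").astype("Int64")
    return PlateReadout(merged)


def normalize_to_controls(readout: PlateReadout) -> NormalizedResponse:
    """NCV per design row: well signal / mean negative-control signal,
    averaged over replicate wells.  Values above 1 are retained."""
    neg = readout.signals(NEGATIVE)
    mu_neg = float(neg.mean())
    if mu_neg <= 1e-12:
        raise ValueError("negative-control mean is zero; normalization undefined")
    treated = readout.wells[readout.wells["role"] == DESIGN].copy()
    treated["ncv"] = treated["signal"].astype(float) / mu_neg
    grouped = treated.groupby(treated["design_row"].astype(int))["ncv"]
    return NormalizedResponse(
        ncv=grouped.mean().sort_index(),
        replicate_sd=grouped.std(ddof=1).sort_index(),
    )


def _control_stats(readout: PlateReadout) -> tuple[float, float, float, float]:
    pos = readout.signals(POSITIVE)
    neg = readout.signals(NEGATIVE)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("Z'/SSMD need >= 2 wells per control group")
    return (
        float(neg.mean()),
        float(neg.std(ddof=1)),
        float(pos.mean()),
        float(pos.std(ddof=1)),
    )


def compute_zprime(readout: PlateReadout) -> float:
    """Assay window Z' = 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|,
    on raw signals with sample (n-1) standard deviations."""
    mu_n, sd_n, mu_p, sd_p = _control_stats(readout)
    window = abs(mu_p - mu_n)
    if window == 0:
        raise ValueError("Z' undefined: positive and negative control means equal")
    return 1.0 - 3.0 * (sd_p + sd_n) / window


def compute_ssmd(readout: PlateReadout) -> float:
    """SSMD = (mean_neg - mean_pos) / sqrt(sd_neg^2 + sd_pos^2)."""
    mu_n, sd_n, mu_p, sd_p = _control_stats(readout)
    denom = float(np.hypot(sd_n, sd_p))
    if denom == 0:
        raise ValueError("SSMD undefined: both control variances are zero")
    return (mu_n - mu_p) / denom


def qc_gate(readout: PlateReadout, threshold: float = ZPRIME_GATE) -> QCMetrics:
    """Pass iff Z' >= threshold (the boundary passes; exclusion is strict
    Z' < threshold).  Failing runs carry no downstream model."""
    z = compute_zprime(readout)
    try:
        s = compute_ssmd(readout)
    except ValueError:
        # zero-variance controls: infinite separation, not a QC failure
        s = float("inf")
    return QCMetrics(zprime=z, ssmd=s, passed=z >= threshold, threshold=threshold)
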