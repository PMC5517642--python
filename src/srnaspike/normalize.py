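"""Standard curves: relative units (RPM, TPM) -> molecules per ug total RNA.

Each spike-in set contributes one calibration point (its measured RPM and
its known input amount); the default fit is least squares of log10(MPU) on
log10(relative), because the dilution series spans several decades and a
linear-scale fit would be dominated by the single largest point.  The same
machinery calibrates mRNA TPMs against ERCC spike-ins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import SpikeInSheet

logger = logging.getLogger(__name__)


def compute_rpm(weighted_count: float, genome_matching_total: float) -> float:
    """Reads per million genome-matching reads (spike-ins excluded from
    the denominator)."""
    if genome_matching_total <= 0:
        raise ValueError("genome_matching_total must be > 0")
    return weighted_count / genome_matching_total * 1e6


@dataclass
class StandardCurve:
    """A fitted relative->absolute calibration with correlation diagnostics."""

    slope: float
    intercept: float
    scale: str  # "log10" or "linear"
    pearson_r: float
    p_value: float
    n_points: int
    platform: str = "srna_rpm"

    def predict(self, relative: float) -> float:
        return to_mpu(self, relative)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "scale": self.scale,
                    "pearson_r": self.pearson_r,
                    "p_value": self.p_value,
                    "n_points": self.n_points,
                    "platform": self.platform,
                }
            ]
        )


def fit_standard_curve(
    points: Sequence[tuple[float, float]],
    scale: str = "log10",
    platform: str = "srna_rpm",
) -> StandardCurve:
    """Least-squares fit of known MPU on the relative unit.

    ``points`` are (relative, known_mpu) pairs.  On the default log10
    scale both coordinates are log-transformed first and non-positive
    points are dropped with a warning.  Pearson r and its two-sided
    p-value are those of the fitted correlation.
    """
    if scale not in {"log10", "linear"}:
        raise ValueError(f"unknown scale {scale!r}")
    pts = [(float(x), float(y)) for x, y in points]
    if scale == "log10":
        usable = [(x, y) for x, y in pts if x > 0 and y > 0]
        dropped = len(pts) - len(usable)
        if dropped:
            logger.warning(
                "dropping %d non-positive calibration points from log fit",
                dropped,
            )
        xs = np.log10([x for x, _ in usable])
        ys = np.log10([y for _, y in usable])
    else:
        usable = pts
        xs = np.array([x for x, _ in usable])
        ys = np.array([y for _, y in usable])
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 usable calibration points, got {len(usable)}"
        )
    fit = sps.linregress(xs, ys)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        scale=scale,
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n_points=len(usable),
        platform=platform,
    )


def to_mpu(curve: StandardCurve, relative: float) -> float:
    """Convert one relative value through the curve; 0 maps to 0 by
    convention on the log scale."""
    if relative < 0:
        raise ValueError("relative abundance must be >= 0")
    if curve.scale == "log10":
        if relative == 0:
            return 0.0
        return float(10 ** (curve.slope * np.log10(relative) + curve.intercept))
    return float(curve.slope * relative + curve.intercept)


def spikein_curve(
    spikein_counts: Mapping[str, float],
    sheet: SpikeInSheet,
    genome_matching_total: float,
    scale: str = "log10",
) -> StandardCurve:
    """Fit the sRNA standard curve from per-set tag counts and the sheet's
    known input amounts.  Sets with zero reads are dropped (logged)."""
    points = []
    for sid, amount in zip(sheet.set_ids, sheet.molecules_per_ug):
        count = spikein_counts.get(sid, 0.0)
        if count <= 0:
            logger.warning("spike-in set %s has no reads; dropped from fit", sid)
            continue
        points.append((compute_rpm(count, genome_matching_total), amount))
    return fit_standard_curve(points, scale=scale, platform="srna_rpm")


def apply_curve(
    families: pd.DataFrame, curve: StandardCurve, column: str = "rpm"
) -> pd.DataFrame:
    """Fill the ``mpu`` column of a family table through the curve."""
    out = families.copy()
    out["mpu"] = [to_mpu(curve, v) for v in out[column]]
    return out


def mrna_to_mpu(
    tpm_table: pd.DataFrame,
    ercc_sheet: pd.DataFrame,
    min_tpm: float = 1.0,
) -> tuple[pd.DataFrame, StandardCurve]:
    """Calibrate mRNA TPMs against ERCC spike-ins and convert to MPU.

    ``tpm_table`` needs columns transcript_id/tpm and must contain the
    ERCC transcripts; ``ercc_sheet`` needs ercc_id/molecules_per_ug.
    Transcripts below ``min_tpm`` keep an undefined (NaN) MPU.
    """
    for col in ("transcript_id", "tpm"):
        if col not in tpm_table.columns:
            raise ValueError(f"tpm_table lacks column {col!r}")
    for col in ("ercc_id", "molecules_per_ug"):
        if col not in ercc_sheet.columns:
            raise ValueError(f"ercc_sheet lacks column {col!r}")
    tpm_of = dict(zip(tpm_table["transcript_id"], tpm_table["tpm"].astype(float)))
    points = [
        (tpm_of[eid], float(mpu))
        for eid, mpu in zip(
            ercc_sheet["ercc_id"], ercc_sheet["molecules_per_ug"]
        )
        if eid in tpm_of and tpm_of[eid] > 0
    ]
    if len(points) < 2:
        raise ValueError(
            f"only {len(points)} ERCC transcripts detected; need >= 2"
        )
    curve = fit_standard_curve(points, scale="log10", platform="mrna_tpm")
    out = tpm_table.copy()
    out["mpu"] = [
        to_mpu(curve, t) if t >= min_tpm else np.nan
        for t in out["tpm"].astype(float)
    ]
    return out, curve
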