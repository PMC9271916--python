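"""Termination efficiency from the dual-fluorescent-reporter assay.

A candidate terminator sits between an upstream GFP and a downstream RFP
gene; read-through produces RFP.  Relative to a negative-control (NC)
construct with no terminator,

    TE = [1 - (RFP/GFP) / (RFP0/GFP0)] * 100  (%)

with all fluorescence blank-subtracted and OD600-normalized.  TE is 0 when
the test ratio equals the NC ratio, 100 at complete termination, and negative
when the insert enhances read-through.

Replicates are aggregated by computing TE per replicate and reporting
mean +/- SD (matching per-culture error bars); blank subtraction precedes
OD normalization; negative normalized fluorescence is floored at 0 and
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import SchemaError

PLATE_COLUMNS = ("sample", "role", "replicate", "gfp", "rfp", "od600")
ROLES = ("test", "negative_control", "positive_control", "blank")


@dataclass(frozen=True)
class ReporterMeasurement:
    sample: str
    gfp: float
    rfp: float
    od600: float
    role: str = "test"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role != "blank" and not self.od600 > 0:
            raise ValueError(f"sample {self.sample!r}: OD600 must be > 0")


@dataclass
class TEResult:
    sample: str
    te: float
    replicates: int
    te_sd: float
    flagged: bool = False  # some fluorescence fell below blank


def normalize(
    m: ReporterMeasurement, blank: ReporterMeasurement
) -> tuple[float, float, bool]:
    """Blank-subtract then OD-normalize; returns (gfp, rfp, floored_flag)."""
    if blank is None:
        raise ValueError("blank measurement required")
    if not m.od600 > 0:
        raise ValueError(f"sample {m.sample!r}: OD600 must be > 0")
    g = (m.gfp - blank.gfp) / m.od600
    r = (m.rfp - blank.rfp) / m.od600
    flagged = g < 0 or r < 0
    return max(g, 0.0), max(r, 0.0), flagged


def compute_te(gfp: float, rfp: float, gfp0: float, rfp0: float) -> float:
    """TE (%) of one normalized test measurement against the NC ratios."""
    if gfp <= 0 or gfp0 <= 0:
        raise ValueError("normalized GFP must be > 0 for TE to be defined")
    nc_ratio = rfp0 / gfp0
    if nc_ratio <= 0:
        raise ValueError("NC RFP/GFP ratio must be > 0")
    return (1.0 - (rfp / gfp) / nc_ratio) * 100.0


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise SchemaError(f"plate table missing column(s): {missing}")
    bad = set(plate["role"]) - set(ROLES)
    if bad:
        raise SchemaError(f"unknown role(s) in plate: {sorted(bad)}")
    nc = plate[plate["role"] == "negative_control"]
    if nc["sample"].nunique() != 1:
        raise SchemaError("plate must contain exactly one negative_control group")
    if not (plate[plate["role"] == "blank"].shape[0] >= 1):
        raise SchemaError("plate must contain at least one blank row")
    return plate


def analyze_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-sample TE (mean +/- SD across replicates) for a whole plate.

    Expects the schema ``sample, role, replicate, gfp, rfp, od600``.
    """
    plate = validate_plate(plate)
    blanks = plate[plate["role"] == "blank"]
    blank = ReporterMeasurement(
        "blank", float(blanks["gfp"].mean()), float(blanks["rfp"].mean()), 1.0, "blank"
    )

    def _norm(row) -> tuple[float, float, bool]:
        m = ReporterMeasurement(
            row["sample"], float(row["gfp"]), float(row["rfp"]),
            float(row["od600"]), row["role"],
        )
        return normalize(m, blank)

    nc_rows = plate[plate["role"] == "negative_control"]
    nc_norm = [_norm(r) for _, r in nc_rows.iterrows()]
    gfp0 = float(np.mean([g for g, _, _ in nc_norm]))
    rfp0 = float(np.mean([r for _, r, _ in nc_norm]))

    out = []
    for sample, grp in plate[plate["role"] != "blank"].groupby("sample", sort=True):
        tes, flagged = [], False
        for _, row in grp.iterrows():
            g, r, fl = _norm(row)
            flagged = flagged or fl
            tes.append(compute_te(g, r, gfp0, rfp0))
        out.append(
            TEResult(
                sample=sample,
                te=float(np.mean(tes)),
                replicates=len(tes),
                te_sd=float(np.std(tes, ddof=1)) if len(tes) > 1 else 0.0,
                flagged=flagged,
            )
        )
    return pd.DataFrame([vars(t) for t in out])


def promoter_te_correlation(pairs: list[tuple[float, float]]) -> tuple[float, float]:
    """Pearson r and least-squares slope of TE against promoter activity."""
    if len(pairs) < 3:
        raise ValueError("need >= 3 (promoter activity, TE) pairs")
    x = np.asarray([p for p, _ in pairs], dtype=float)
    y = np.asarray([t for _, t in pairs], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant input: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    slope = float(stats.linregress(x, y).slope)
    return r, slope
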