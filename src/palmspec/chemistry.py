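"""AOAC iodometric titration chemistry for peroxide and iodine value.

Forward formulas convert titration endpoints to the two quality indices;
the algebraic inverses synthesise consistent titration endpoints from known
index values, so simulated reference tables and simulated titration sheets
agree exactly.

PV (meq O2/kg) = (S - B) * N * 1000 / W        (AOAC 965.33)
IV (g I2/100g) = (B - S) * M * 12.69 / W       (AOAC 993.20, Wijs)

with S the sample titre (mL), B the blank titre (mL), N/M the thiosulfate
normality/molarity, and W the sample mass (g). 12.69 converts mol of
thiosulfate to grams of iodine per 100 g of oil and is treated as exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

IODINE_FACTOR = 12.69  # g I2 per 100 g oil per (mL * mol/L / g)


@dataclass(frozen=True)
class TitrationRecord:
    """One titration: sample/blank volumes (mL), titrant strength, oil mass (g)."""

    S: float
    B: float
    N_or_M: float
    W: float

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError(f"sample mass W must be positive, got {self.W}")
        if self.S < 0 or self.B < 0:
            raise ValueError("titration volumes must be non-negative")
        if self.N_or_M <= 0:
            raise ValueError(f"titrant normality/molarity must be positive, got {self.N_or_M}")


def peroxide_value(rec: TitrationRecord) -> float:
    """Peroxide value in meq O2/kg from an iodometric titration.

    Requires S >= B: the sample must consume at least as much thiosulfate
    as the blank, otherwise the titration is physically impossible.
    """
    if rec.S < rec.B:
        raise ValueError(
            f"sample titre S={rec.S} below blank B={rec.B}: negative peroxide is impossible"
        )
    return (rec.S - rec.B) * rec.N_or_M * 1000.0 / rec.W


def iodine_value(rec: TitrationRecord) -> float:
    """Iodine value in g I2/100 g from a Wijs titration (blank minus sample)."""
    if rec.B < rec.S:
        raise ValueError(
            f"blank titre B={rec.B} below sample S={rec.S}: negative iodine value is impossible"
        )
    return (rec.B - rec.S) * rec.N_or_M * IODINE_FACTOR / rec.W


def titration_from_pv(pv: float, N: float = 0.1, W: float = 5.0, B: float = 0.2) -> float:
    """Sample titre S (mL) that reproduces ``pv`` under the forward formula."""
    if pv < 0:
        raise ValueError(f"peroxide value must be non-negative, got {pv}")
    if N <= 0 or W <= 0:
        raise ValueError("normality N and mass W must be positive")
    return B + pv * W / (N * 1000.0)


def titration_from_iv(iv: float, M: float = 0.1, W: float = 2.0, B: float = 25.0) -> float:
    """Sample titre S (mL) that reproduces ``iv`` under the forward formula.

    The blank must be large enough that the implied S stays non-negative.
    """
    if iv < 0:
        raise ValueError(f"iodine value must be non-negative, got {iv}")
    if M <= 0 or W <= 0:
        raise ValueError("molarity M and mass W must be positive")
    S = B - iv * W / (M * IODINE_FACTOR)
    if S < 0:
        raise ValueError(
            f"blank B={B} mL too small for iv={iv} (implied sample titre {S:.4f} mL < 0)"
        )
    return S


def read_titration_csv(path: str | Path) -> dict[str, TitrationRecord]:
    """Read a titration table (sample_id, S, B, N_or_M, W) keyed by sample id."""
    df = pd.read_csv(path)
    return {
        str(row.sample_id): TitrationRecord(S=row.S, B=row.B, N_or_M=row.N_or_M, W=row.W)
        for row in df.itertuples()
    }


def write_titration_csv(records: dict[str, TitrationRecord], path: str | Path) -> None:
    rows = [
        {"sample_id": sid, "S": r.S, "B": r.B, "N_or_M": r.N_or_M, "W": r.W}
        for sid, r in records.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
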