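"""Derived kinetic quantities for a carboxylase/oxygenase.

The specificity factor S_C/O = (V_C/K_C)/(V_O/K_O) relates the four measured
parameters; identifying V_C/V_O with the per-site turnover numbers
kcat_C/kcat_O lets the oxygenase turnover be derived from the other four:

    kcat_O = kcat_C * K_O / (S_C/O * K_C)

Values are held at full precision internally; rounding (half-up, to the
reported precision) happens only at report time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd


def round_half_up(value: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class KineticsRecord:
    enzyme: str
    oligomeric_state: str        # e.g. L6, L2
    kcat_c: float                # carboxylase turnover, s^-1
    K_c: float                   # CO2 Michaelis constant, uM
    S_co: float                  # specificity factor, dimensionless
    K_o: float                   # O2 Michaelis constant, uM
    kcat_o: float | None = None  # oxygenase turnover, s^-1 (measured or derived)

    def complete(self) -> bool:
        return all(v is not None and v == v  # NaN check
                   for v in (self.kcat_c, self.K_c, self.S_co, self.K_o))


def kcat_o_from_specificity(kcat_c: float, K_c: float, S_co: float, K_o: float) -> float:
    """Oxygenase turnover implied by the specificity relation (s^-1)."""
    for name, v in (("kcat_c", kcat_c), ("K_c", K_c), ("S_co", S_co), ("K_o", K_o)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v!r}")
    return kcat_c * K_o / (S_co * K_c)


def fold_change(mutant_value: float, wildtype_value: float) -> float:
    """Mutant / wild-type ratio."""
    if wildtype_value <= 0:
        raise ValueError("wild-type value must be positive")
    return mutant_value / wildtype_value


def percent_decrease(mutant_value: float, wildtype_value: float) -> float:
    """(1 - mutant/wild-type) x 100."""
    if wildtype_value <= 0:
        raise ValueError("wild-type value must be positive")
    return (1.0 - mutant_value / wildtype_value) * 100.0


def read_kinetics_tsv(path: str | Path) -> list[KineticsRecord]:
    """Read a header TSV: enzyme, state, kcat_c, K_c, S_co, K_o[, kcat_o]."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        records.append(KineticsRecord(
            enzyme=str(row["enzyme"]),
            oligomeric_state=str(row.get("state", "")),
            kcat_c=float(row["kcat_c"]), K_c=float(row["K_c"]),
            S_co=float(row["S_co"]), K_o=float(row["K_o"]),
            kcat_o=float(row["kcat_o"]) if "kcat_o" in row and pd.notna(row["kcat_o"])
            else None))
    return records


def kinetics_table(records: list[KineticsRecord], reference: str) -> pd.DataFrame:
    """Derived columns per enzyme: kcat_o, fold-changes vs the reference for
    S_C/O and K_O, and percent decrease in kcat_C.

    Report-time rounding: kcat_o and fold-changes to 2 decimals, percent
    decrease to the nearest integer.  Rows with missing fields are skipped
    with a warning.
    """
    by_name = {r.enzyme: r for r in records}
    if reference not in by_name:
        raise ValueError(f"reference enzyme {reference!r} not in table")
    ref = by_name[reference]
    if not ref.complete():
        raise ValueError(f"reference enzyme {reference!r} has missing fields")

    rows = []
    for rec in records:
        if not rec.complete():
            warnings.warn(f"row {rec.enzyme!r} skipped: missing fields", stacklevel=2)
            continue
        kcat_o = rec.kcat_o if rec.kcat_o is not None else kcat_o_from_specificity(
            rec.kcat_c, rec.K_c, rec.S_co, rec.K_o)
        rows.append({
            "enzyme": rec.enzyme,
            "state": rec.oligomeric_state,
            "kcat_c": rec.kcat_c, "K_c": rec.K_c,
            "S_co": rec.S_co, "K_o": rec.K_o,
            "kcat_o_derived": round_half_up(kcat_o, 2),
            "S_co_fold_vs_ref": round_half_up(fold_change(rec.S_co, ref.S_co), 2),
            "K_o_fold_vs_ref": round_half_up(fold_change(rec.K_o, ref.K_o), 2),
            "kcat_c_decrease_pct": int(round_half_up(
                percent_decrease(rec.kcat_c, ref.kcat_c), 0)),
        })
    return pd.DataFrame(rows)


def kinetics_report_json(table: pd.DataFrame) -> str:
    return json.dumps(table.to_dict(orient="records"), indent=2) + "\n"
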