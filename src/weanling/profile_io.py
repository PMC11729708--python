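"""Reading, validation, and collagen-quality filtering of incremental dentine data.

The working container for a set of dentine profiles is a plain pandas
DataFrame with one row per increment and the canonical columns listed in
:data:`REQUIRED_COLUMNS`.  Increments are indexed crown-to-root within an
individual, with positions in millimetres measured from the crown as
half-open intervals [start, end).  Isotope ratios are per-mil values
(delta13C vs VPDB, delta15N vs AIR); pct_C / pct_N are mass percentages of
carbon and nitrogen in the extracted collagen.

Quality control follows standard collagen-preservation practice: each
increment is screened on the atomic C:N ratio and elemental floors, and an
individual is excluded wholesale when too many of its increments fail —
exclusion operates on individuals, not single increments, because a profile
with unreliable chemistry cannot support a life-history reconstruction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "ValidationError",
    "QCCriteria",
    "QCReport",
    "read_increments",
    "write_table",
    "validate_increments",
    "cn_atomic_ratio",
    "qc_filter",
]

#: Canonical column order for increment tables.
REQUIRED_COLUMNS = (
    "individual_id",
    "site",
    "tooth",
    "increment_index",
    "position_start_mm",
    "position_end_mm",
    "d13C",
    "d15N",
    "pct_C",
    "pct_N",
)

# Atomic masses of C and N (u); the atomic C:N ratio is
# (pct_C / 12.011) / (pct_N / 14.007).
_MASS_C = 12.011
_MASS_N = 14.007


class SchemaError(ValueError):
    """A required column cannot be resolved in the input table."""


class ValidationError(ValueError):
    """An increment table violates a structural invariant."""


@dataclass(frozen=True)
class QCCriteria:
    """Collagen-preservation screening thresholds.

    Defaults are the conventional collagen acceptance window: atomic C:N in
    [2.9, 3.6] with elemental floors of 13 mass-% carbon and 4.8 mass-%
    nitrogen.  ``max_failed_fraction`` is the tolerated fraction of failing
    increments before the whole individual is excluded.
    """

    cn_atomic_min: float = 2.9
    cn_atomic_max: float = 3.6
    pct_C_min: float = 13.0
    pct_N_min: float = 4.8
    max_failed_fraction: float = 0.5

    def __post_init__(self):
        if not self.cn_atomic_min < self.cn_atomic_max:
            raise ValueError("cn_atomic_min must be < cn_atomic_max")
        if self.pct_C_min <= 0 or self.pct_N_min <= 0:
            raise ValueError("elemental floors must be > 0")
        if not 0.0 <= self.max_failed_fraction <= 1.0:
            raise ValueError("max_failed_fraction must be in [0, 1]")


@dataclass
class QCReport:
    """Outcome of :func:`qc_filter`.

    Attributes
    ----------
    increments
        Per-increment table with ``qc_pass`` flag and ``qc_reasons``.
    individuals
        Per-individual table with failure counts and ``status``
        (``retained`` / ``excluded``).
    criteria
        The :class:`QCCriteria` applied.
    """

    increments: pd.DataFrame
    individuals: pd.DataFrame
    criteria: QCCriteria = field(default_factory=QCCriteria)

    @property
    def retained_ids(self) -> list[str]:
        keep = self.individuals["status"] == "retained"
        return list(self.individuals.loc[keep, "individual_id"])

    def summary(self) -> dict:
        return {
            "n_individuals": int(len(self.individuals)),
            "n_retained": int((self.individuals["status"] == "retained").sum()),
            "n_excluded": int((self.individuals["status"] == "excluded").sum()),
            "excluded_ids": list(
                self.individuals.loc[
                    self.individuals["status"] == "excluded", "individual_id"
                ]
            ),
            "criteria": self.criteria.__dict__,
        }

    def write(self, increments_csv, individuals_csv, summary_json=None) -> None:
        self.increments.to_csv(increments_csv, index=False)
        self.individuals.to_csv(individuals_csv, index=False)
        if summary_json is not None:
            with open(summary_json, "w") as fh:
                json.dump(self.summary(), fh, indent=2)


def cn_atomic_ratio(pct_C, pct_N):
    """Atomic C:N ratio from mass percentages of carbon and nitrogen.

    Both arguments must be strictly positive; accepts scalars or arrays.
    """
    pct_C = np.asarray(pct_C, dtype=float)
    pct_N = np.asarray(pct_N, dtype=float)
    if np.any(pct_C <= 0) or np.any(pct_N <= 0):
        raise ValueError("pct_C and pct_N must be > 0")
    out = (pct_C / _MASS_C) / (pct_N / _MASS_N)
    return float(out) if out.ndim == 0 else out


def read_increments(path, schema: dict | None = None) -> pd.DataFrame:
    """Read and validate an increment CSV.

    Parameters
    ----------
    path
        CSV file with a header row.  Lines starting with ``#`` are ignored.
    schema
        Optional mapping from canonical column names to the file's column
        names, e.g. ``{"d15N": "δ15N (AIR)"}``.  Unmapped canonical names
        are looked up verbatim.

    Returns
    -------
    DataFrame with the canonical columns, sorted by individual and
    increment index, validated against the structural invariants.
    """
    raw = pd.read_csv(path, comment="#")
    schema = schema or {}
    rename = {}
    for canon in REQUIRED_COLUMNS:
        source = schema.get(canon, canon)
        if source not in raw.columns:
            raise SchemaError(
                f"column {source!r} (for {canon!r}) not found in {path}"
            )
        rename[source] = canon
    df = raw.rename(columns=rename)[list(REQUIRED_COLUMNS)].copy()
    df["increment_index"] = df["increment_index"].astype(int)
    for col in REQUIRED_COLUMNS[4:]:
        df[col] = df[col].astype(float)
    df = df.sort_values(["individual_id", "increment_index"], kind="stable")
    df = df.reset_index(drop=True)
    validate_increments(df)
    return df


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a pipeline table as CSV, optionally with a ``#`` header line."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def validate_increments(df: pd.DataFrame) -> None:
    """Check the structural invariants of an increment table.

    Raises :class:`ValidationError` naming the offending individual and
    increment on the first violation found.
    """
    if len(df) == 0:
        return
    for col, lo, hi in [("d13C", -40.0, 0.0), ("d15N", 0.0, 30.0)]:
        bad = df[(df[col] < lo) | (df[col] > hi)]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"{col}={row[col]} outside [{lo}, {hi}] for individual "
                f"{row['individual_id']!r} increment {int(row['increment_index'])}"
            )
    for col in ("pct_C", "pct_N"):
        bad = df[(df[col] <= 0) | (df[col] > 100)]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"{col}={row[col]} outside (0, 100] for individual "
                f"{row['individual_id']!r} increment {int(row['increment_index'])}"
            )
    for ind, grp in df.groupby("individual_id", sort=False):
        idx = grp["increment_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ValidationError(
                f"increment_index not contiguous from 1 for individual {ind!r}"
            )
        start = grp["position_start_mm"].to_numpy()
        end = grp["position_end_mm"].to_numpy()
        if np.any(end <= start):
            k = int(idx[np.argmax(end <= start)])
            raise ValidationError(
                f"position_end_mm <= position_start_mm for individual {ind!r} "
                f"increment {k}"
            )
        if np.any(start[1:] < end[:-1] - 1e-9):
            k = int(idx[1:][np.argmax(start[1:] < end[:-1] - 1e-9)])
            raise ValidationError(
                f"increments overlap or are out of order for individual {ind!r} "
                f"at increment {k}"
            )


def qc_filter(df: pd.DataFrame, criteria: QCCriteria | None = None) -> QCReport:
    """Screen increments against collagen-preservation criteria.

    Each increment is flagged on atomic C:N and elemental floors; an
    individual is excluded when its failing fraction exceeds
    ``criteria.max_failed_fraction``.  Deterministic, idempotent, and
    order-independent within an individual.
    """
    if len(df) == 0:
        raise ValidationError("qc_filter requires a nonempty profile table")
    criteria = criteria or QCCriteria()
    inc = df.copy()
    cn = cn_atomic_ratio(inc["pct_C"].to_numpy(), inc["pct_N"].to_numpy())
    inc["cn_atomic"] = cn

    reasons = []
    for i in range(len(inc)):
        r = []
        if not criteria.cn_atomic_min <= cn[i] <= criteria.cn_atomic_max:
            r.append(
                f"C:N {cn[i]:.2f} outside "
                f"[{criteria.cn_atomic_min}, {criteria.cn_atomic_max}]"
            )
        if inc["pct_C"].iat[i] < criteria.pct_C_min:
            r.append(f"%C {inc['pct_C'].iat[i]:.1f} < {criteria.pct_C_min}")
        if inc["pct_N"].iat[i] < criteria.pct_N_min:
            r.append(f"%N {inc['pct_N'].iat[i]:.1f} < {criteria.pct_N_min}")
        reasons.append("; ".join(r))
    inc["qc_pass"] = [r == "" for r in reasons]
    inc["qc_reasons"] = reasons

    rows = []
    for ind, grp in inc.groupby("individual_id", sort=False):
        n = len(grp)
        n_failed = int((~grp["qc_pass"]).sum())
        frac = n_failed / n
        rows.append(
            {
                "individual_id": ind,
                "site": grp["site"].iat[0],
                "n_increments": n,
                "n_failed": n_failed,
                "failed_fraction": frac,
                "status": "excluded"
                if frac > criteria.max_failed_fraction
                else "retained",
            }
        )
    individuals = pd.DataFrame(rows)
    return QCReport(increments=inc, individuals=individuals, criteria=criteria)
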