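"""File dialects: vital-rates tables, LRS matrices, summaries, reports.

All inputs are delimited text (comma or tab, autodetected by extension) with
a header row.  The missing-data token (default ``NA``, case-insensitive)
distinguishes "not observed" from "observed, zero offspring" -- the
distinction matters for lifetime matrices, where an observed 0 is a breeding
attempt that counts toward age-at-death.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import VitalRates
from .scaling import GroupRawStats


__all__ = [
    "read_vital_rates",
    "read_lrs_matrix",
    "read_lifetime_summary",
    "write_lrs_matrix",
    "write_vital_rates",
    "write_report",
]

_COLUMN_ALIASES = {
    "v_x": "v", "vx": "v",
    "l_x": "l", "lx": "l",
    "kbar_x": "kbar", "k_bar": "kbar", "mean": "kbar",
    "s2_kx": "s2", "s2_k": "s2", "var": "s2",
    "d_q": "D", "dq": "D", "d": "D",
    "n_x": "N_x", "nx": "N_x",
}


def _read_table(path, na_token: str = "NA") -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, na_values=[na_token, na_token.lower(),
                                               na_token.upper()],
                     keep_default_na=True)
    if df.empty:
        raise ValueError(f"{path}: file contains no data rows")
    df.columns = [_COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower())
                  for c in df.columns]
    return df


def _parse_ages(raw) -> tuple[np.ndarray, bool]:
    """Integer ages from labels; a trailing '+' on the last marks a plus-group."""
    labels = [str(a).strip() for a in raw]
    plus = [lab.endswith("+") for lab in labels]
    if any(plus[:-1]):
        raise ValueError("only the last age class may be a plus-group")
    ages = np.array([int(lab.rstrip("+")) for lab in labels])
    if np.any(np.diff(ages) <= 0):
        bad = list(np.flatnonzero(np.diff(ages) <= 0) + 2)
        raise ValueError(f"ages must be strictly increasing (rows {bad})")
    return ages, plus[-1]


def read_vital_rates(
    path, N1: int, na_token: str = "NA"
) -> tuple[VitalRates, list[GroupRawStats]]:
    """Read a per-sex vital-rates table.

    Required columns: ``age``, ``v`` or ``l``, ``kbar``, ``s2`` (an optional
    ``b_relative`` column is carried through).  Rows whose ``s2`` is missing
    are treated as juvenile classes: they contribute survivorship but no
    ANOVA group.  Survivorship is chained from ``v`` where ``l`` is missing
    (explicit ``l`` entries -- e.g. the pooled plus-group -- take precedence).

    Returns the adult-ages :class:`VitalRates` (with ``N1`` attached) and the
    per-age raw statistics, aligned.
    """
    df = _read_table(path, na_token)
    if "age" not in df.columns:
        raise ValueError("missing required column: age")
    if "kbar" not in df.columns or "s2" not in df.columns:
        raise ValueError("missing required column(s): kbar and/or s2")
    if "v" not in df.columns and "l" not in df.columns:
        raise ValueError("need a v or l column")
    ages, plus_group = _parse_ages(df["age"])

    n = len(df)
    l = df["l"].to_numpy(dtype=float) if "l" in df.columns else np.full(n, np.nan)
    v = df["v"].to_numpy(dtype=float) if "v" in df.columns else None
    if v is not None:
        if np.isnan(l[0]):
            l[0] = 1.0
        for i in range(n - 1):
            if np.isnan(l[i + 1]):
                l[i + 1] = l[i] * v[i]
    if np.any(np.isnan(l)):
        rows = list(np.flatnonzero(np.isnan(l)) + 2)
        raise ValueError(f"survivorship underdetermined at rows {rows}")
    if v is None:
        # back-derive annual survival from successive survivorship ratios
        v = np.full(n, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            v[:-1] = l[1:] / l[:-1]

    for col in ("kbar", "s2"):
        vals = df[col].to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            rows = list(np.flatnonzero(vals < 0) + 2)
            raise ValueError(f"negative {col} at rows {rows}")

    adult = ~df["s2"].isna().to_numpy()
    if not adult.any():
        raise ValueError("no adult age classes (every s2 is missing)")

    vr = VitalRates(ages=ages[adult], l=l[adult], N1=N1,
                    plus_group=plus_group,
                    v=v[adult] if v is not None else None)
    raw_age_labels = [str(a).strip() for a in df["age"]]
    N_x = np.rint(N1 * l).astype(int)
    stats = [
        GroupRawStats(label=raw_age_labels[i], n=int(N_x[i]),
                      kbar=float(df["kbar"].iloc[i]),
                      s2=float(df["s2"].iloc[i]))
        for i in np.flatnonzero(adult)
    ]
    return vr, stats


def read_lrs_matrix(path, na_token: str = "NA") -> pd.DataFrame:
    """Read a per-individual lifetime matrix (id column + one column per age).

    Entries are integer offspring counts or the missing token.  Rows with no
    observed entry are rejected (their age-at-death is undefined).
    """
    df = _read_table(path, na_token)
    id_col = df.columns[0]
    matrix = df.set_index(id_col)
    values = matrix.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    bad = ~observed.any(axis=1)
    if bad.any():
        raise ValueError(f"all-missing rows for ids: {list(matrix.index[bad])}")
    seen = values[observed]
    if not np.allclose(seen, np.rint(seen)) or np.any(seen < 0):
        raise ValueError("offspring counts must be non-negative integers")
    return matrix


def read_lifetime_summary(
    path, na_token: str = "NA"
) -> tuple[list[GroupRawStats], np.ndarray | None]:
    """Read a per-age-at-death summary table (q, D, kbar, s2[, N_x]).

    This dialect lets published group summaries drive the full lifetime
    pipeline when per-individual data are unavailable.  Returns the group
    statistics and the reconstructed census vector if an ``N_x`` column is
    present.
    """
    df = _read_table(path, na_token)
    required = {"q", "D", "kbar", "s2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    stats = [
        GroupRawStats(label=int(row.q), n=int(row.D),
                      kbar=float(row.kbar), s2=float(row.s2))
        for row in df.itertuples()
    ]
    N_x = df["N_x"].to_numpy(dtype=int) if "N_x" in df.columns else None
    return stats, N_x


def write_lrs_matrix(matrix: pd.DataFrame, path, na_token: str = "NA") -> None:
    """Write a lifetime matrix in the dialect :func:`read_lrs_matrix` reads."""
    out = matrix.copy()
    # keep observed counts as integers in the text file
    out = out.astype("Int64")
    out.to_csv(path, na_rep=na_token)


def write_vital_rates(path, ages, v, l, kbar, s2, na_token: str = "NA") -> None:
    """Write a vital-rates table in the dialect :func:`read_vital_rates` reads."""
    df = pd.DataFrame({"age": ages, "v": v, "l": l, "kbar": kbar, "s2": s2})
    df.to_csv(path, index=False, na_rep=na_token)


def write_report(report: dict, path) -> None:
    """Write a machine-readable JSON report next to a human-readable table."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)
        fh.write("\n")
    txt = path.with_suffix(".txt")
    with open(txt, "w") as fh:
        for key, value in report.items():
            if isinstance(value, list) and value and isinstance(value[0], dict):
                fh.write(f"\n{key}:\n")
                fh.write(pd.DataFrame(value).to_string(index=False,
                                                       float_format="%.4g"))
                fh.write("\n")
            else:
                fh.write(f"{key}: {value}\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)!r}")
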