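"""Delimited-table readers/writers and the GROMACS XVG dialect.

All tables are plain text, comma- or whitespace-delimited, with an optional
single header line.  Comment lines start with ``#`` (or ``@`` in XVG files).
Numbers round-trip losslessly at 17 significant digits.  Schemas:

========== =================================== =========================
name       required columns                    optional columns
========== =================================== =========================
micelle_dg n (int or ``inf``), dg [kJ/mol]     sigma [kJ/mol]
eos        gamma [nm^-2], pi [mN/m]            sigma [mN/m]
tension    gamma [nm^-2], tension [mN/m]       sigma [mN/m]
isotherm   c0 [M], gamma [nm^-2]               pi [mN/m]
========== =================================== =========================

The ``n`` column of ``micelle_dg`` accepts the token ``inf`` for the
infinite-cylinder (asymptotic) datum.
"""

from __future__ import annotations

import math
import re
import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ParseError, SchemaError

_SPLIT = re.compile(r"[,\s]+")

SCHEMAS: dict[str, dict] = {
    "micelle_dg": {
        "columns": ["n", "dg", "sigma"],
        "required": 2,
        "units": ["1", "kJ/mol", "kJ/mol"],
    },
    "eos": {
        "columns": ["gamma", "pi", "sigma"],
        "required": 2,
        "units": ["nm^-2", "mN/m", "mN/m"],
    },
    "tension": {
        "columns": ["gamma", "tension", "sigma"],
        "required": 2,
        "units": ["nm^-2", "mN/m", "mN/m"],
    },
    "isotherm": {
        "columns": ["c0", "gamma", "pi"],
        "required": 2,
        "units": ["M", "nm^-2", "mN/m"],
    },
}


def _parse_token(tok: str, allow_inf: bool):
    t = tok.strip().lower()
    if allow_inf and t in {"inf", "infinity", "+inf"}:
        return math.inf
    return float(tok)


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a delimited table into a DataFrame with the schema's column names.

    Raises :class:`ParseError` (with the 1-based line number) on malformed
    rows and :class:`SchemaError` on missing columns or invariant violations
    (negative coverage/concentration, aggregation number < 1).
    """
    if schema not in SCHEMAS:
        raise InvalidParameterError(
            f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}"
        )
    spec = SCHEMAS[schema]
    names, n_req = spec["columns"], spec["required"]
    allow_inf_col = 0 if schema == "micelle_dg" else None

    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("@"):
                continue
            tokens = [t for t in _SPLIT.split(line) if t]
            if not rows and ncols is None:
                # a non-numeric first data line is a header
                try:
                    _parse_token(tokens[0], allow_inf_col == 0)
                except ValueError:
                    ncols = len(tokens)
                    continue
            values = []
            for j, tok in enumerate(tokens):
                try:
                    values.append(_parse_token(tok, allow_inf_col == j))
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: cannot parse {tok!r} as a number",
                        line_number=lineno,
                    ) from None
            if ncols is None:
                ncols = len(values)
            elif len(values) != ncols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {ncols} columns, got "
                    f"{len(values)}",
                    line_number=lineno,
                )
            rows.append(values)

    if not rows:
        raise SchemaError(f"{path}: no data rows")
    ncols = len(rows[0])
    if ncols < n_req or ncols > len(names):
        raise SchemaError(
            f"{path}: schema {schema!r} needs {n_req}-{len(names)} columns, "
            f"got {ncols}"
        )
    df = pd.DataFrame(rows, columns=names[:ncols])
    _check_invariants(df, schema, path)
    return df


def _check_invariants(df: pd.DataFrame, schema: str, path) -> None:
    if schema == "micelle_dg":
        if (df["n"] < 1).any():
            raise SchemaError(f"{path}: aggregation numbers must be >= 1")
    if schema in ("eos", "tension", "isotherm"):
        if (df["gamma"] < 0).any():
            raise SchemaError(f"{path}: coverages must be >= 0")
    if schema == "isotherm" and (df["c0"] < 0).any():
        raise SchemaError(f"{path}: concentrations must be >= 0")
    if "sigma" in df.columns and (df["sigma"] < 0).any():
        raise SchemaError(f"{path}: uncertainties must be >= 0")


def write_table(path, df: pd.DataFrame, schema: str, meta: dict | None = None) -> None:
    """Write a DataFrame under a named schema, with a unit-annotated header.

    Optional ``meta`` entries (parameters, seed, versions) are echoed as
    ``# key = value`` comment lines for provenance.
    """
    if schema not in SCHEMAS:
        raise InvalidParameterError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    cols = [c for c in spec["columns"] if c in df.columns]
    if len(cols) < spec["required"]:
        raise SchemaError(f"DataFrame lacks required columns for schema {schema!r}")
    units = dict(zip(spec["columns"], spec["units"]))
    with open(path, "w") as fh:
        if meta:
            for key, value in meta.items():
                fh.write(f"# {key} = {value}\n")
        fh.write(" ".join(f"{c}[{units[c]}]" for c in cols) + "\n")
        for _, row in df[cols].iterrows():
            fh.write(" ".join(_fmt(row[c]) for c in cols) + "\n")


def _fmt(x: float) -> str:
    if math.isinf(x):
        return "inf"
    return f"{x:.17g}"


def read_xvg(path) -> np.ndarray:
    """Read a GROMACS-style XVG time series (lines starting ``#``/``@`` skipped).

    Returns a float array of shape (n_rows, n_cols).
    """
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line[0] in "#@":
                continue
            tokens = [t for t in _SPLIT.split(line) if t]
            try:
                values = [float(t) for t in tokens]
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: malformed XVG row", line_number=lineno
                ) from None
            if ncols is None:
                ncols = len(values)
            elif len(values) != ncols:
                raise ParseError(
                    f"{path}: line {lineno}: inconsistent column count",
                    line_number=lineno,
                )
            rows.append(values)
    if not rows:
        raise SchemaError(f"{path}: no data rows in XVG file")
    return np.asarray(rows, dtype=float)


def block_average(values, n_blocks: int = 5) -> tuple[float, float]:
    """Mean and standard error of a correlated time series by block averaging.

    The series is split into ``n_blocks`` contiguous blocks (any remainder at
    the start is dropped); the standard error is the standard deviation of
    block means over sqrt(n_blocks).
    """
    values = np.asarray(values, dtype=float).ravel()
    if n_blocks < 2:
        raise InvalidParameterError(f"n_blocks must be >= 2, got {n_blocks!r}")
    if values.size < n_blocks:
        raise InvalidParameterError(
            f"need at least {n_blocks} samples, got {values.size}"
        )
    per = values.size // n_blocks
    trimmed = values[values.size - per * n_blocks :]
    means = trimmed.reshape(n_blocks, per).mean(axis=1)
    return float(means.mean()), float(means.std(ddof=1) / math.sqrt(n_blocks))
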