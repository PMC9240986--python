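"""Report formatting: percentage rounding, p-value display, table rendering.

Percentages in reports are rounded half-up to one decimal place; p-values
are printed to two decimals and as "<.0001" below 1e-4.  Every percentage
is recomputed from its numerator and denominator at render time — the
reporting layer never drifts from the counts.
"""

from __future__ import annotations

import decimal
import io
from pathlib import Path

import pandas as pd


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), not banker's rounding."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """numerator / denominator as a percent, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for a zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def format_p(p: float) -> str:
    """Two-decimal p-value display; '<.0001' below 1e-4."""
    if p < 1e-4:
        return "<.0001"
    return f"{round_half_up(p, 2):.2f}" if p >= 0.005 else f"{p:.4f}".rstrip("0")


def frame_to_markdown(df: pd.DataFrame, index: bool = False) -> str:
    """Minimal GitHub-style markdown table (no external renderer)."""
    if index:
        df = df.reset_index()
    cols = [str(c) for c in df.columns]
    rows = [[("" if pd.isna(v) else str(v)) for v in row] for row in df.itertuples(index=False)]
    widths = [max(len(c), *(len(r[i]) for r in rows)) if rows else len(c) for i, c in enumerate(cols)]
    def fmt(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    lines = [fmt(cols), "| " + " | ".join("-" * w for w in widths) + " |"]
    lines.extend(fmt(r) for r in rows)
    return "\n".join(lines) + "\n"


def write_frame(df: pd.DataFrame, path: str | Path, fmt: str = "csv", index: bool = False) -> None:
    """Write a report table as csv, json (records) or md."""
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=index)
    elif fmt == "json":
        out = df.reset_index() if index else df
        path.write_text(out.to_json(orient="records", indent=2) + "\n")
    elif fmt == "md":
        path.write_text(frame_to_markdown(df, index=index))
    else:
        raise ValueError(f"unknown report format: {fmt!r}")


def frame_to_text(df: pd.DataFrame, index: bool = False) -> str:
    buf = io.StringIO()
    df.to_string(buf, index=index)
    return buf.getvalue() + "\n"
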