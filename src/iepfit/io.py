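"""Reading samples from plain-text files."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .distribution import PositiveSample

__all__ = ["read_sample"]


def read_sample(path, decimal_comma: bool = False) -> PositiveSample:
    """Read a single column of positive reals, one value per line.

    A lone delimited column (whitespace, comma, semicolon or tab) is also
    accepted.  ``decimal_comma=True`` converts comma decimal separators
    before parsing.  Non-numeric or non-positive entries are rejected
    with their line number.
    """
    text = Path(path).read_text()
    values = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if decimal_comma:
            line = line.replace(",", ".")
        token = line.replace(";", " ").replace(",", " ").replace("\t", " ").split()
        if len(token) != 1:
            raise ValueError(f"line {lineno}: expected a single value, got {raw!r}")
        try:
            value = float(token[0])
        except ValueError:
            raise ValueError(f"line {lineno}: not a number: {raw!r}") from None
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"line {lineno}: value must be positive, got {value!r}")
        values.append(value)
    if not values:
        raise ValueError(f"no data found in {path}")
    return PositiveSample(np.asarray(values))
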