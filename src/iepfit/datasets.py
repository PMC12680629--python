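"""Bundled regional COVID-19 case-fatality-rate datasets.

One cumulative case fatality rate (confirmed deaths / confirmed cases,
in percent) per country, grouped by WHO region or OECD membership.  The
values are packaged verbatim as plain-text fixtures; the OECD source
printed decimal commas, normalized to dot-decimal at packaging time.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .distribution import PositiveSample

__all__ = ["REGION_CODES", "RegionDataset", "load_region"]

REGION_CODES = ("AFR", "EMR", "EUR", "AMR", "SEAR", "WPR", "OECD")


@dataclass(frozen=True)
class RegionDataset:
    region_code: str
    sample: PositiveSample

    @property
    def n(self) -> int:
        return self.sample.n


def load_region(code: str) -> RegionDataset:
    """Load a bundled regional CFR dataset by code (e.g. "AFR"); cached."""
    code = code.upper()
    if code not in REGION_CODES:
        raise KeyError(f"unknown region code {code!r}; choose from {REGION_CODES}")
    return _load_region_cached(code)


@lru_cache(maxsize=None)
def _load_region_cached(code: str) -> RegionDataset:
    text = resources.files("iepfit.data").joinpath(f"{code.lower()}.tsv").read_text()
    values = [
        float(line) for line in text.splitlines() if line.strip() and not line.startswith("#")
    ]
    return RegionDataset(region_code=code, sample=PositiveSample(np.asarray(values)))
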