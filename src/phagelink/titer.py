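"""Plaque-count arithmetic for serial-dilution spot assays and EOP.

A spot assay drops a small volume (default 3.5 uL) of each ten-fold
dilution of a phage stock onto a bacterial lawn.  Plaques are counted at
dilutions where the count falls in the open window 1 < n < 20; each such
spot yields an independent titer estimate

    titer = n * base**exponent / volume_mL        [PFU/mL]

with Poisson counting error sd = sqrt(n) scaled identically.  Qualifying
spots are combined by inverse-variance weighting.  An all-zero series
returns a flagged one-sided detection bound instead of a titer.

The efficiency of plating (EOP) is the ratio of a phage's titer on a test
host to its titer on a reference host.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .uncertain import UncertainValue, uv_ratio

__all__ = [
    "Spot",
    "SpotSeries",
    "TiterMeasurement",
    "titer_from_spots",
    "eop",
    "read_spot_csv",
    "titers_to_frame",
]


@dataclass(frozen=True)
class Spot:
    """One droplet: plaque count observed at ``dilution_base**exponent``."""

    exponent: int
    count: int
    replicate: int | str = 0

    def __post_init__(self) -> None:
        if self.count < 0 or int(self.count) != self.count:
            raise ValueError(f"plaque count must be a non-negative integer, got {self.count}")


@dataclass
class SpotSeries:
    """A serial-dilution spotting series for one (sample, host) pair."""

    spots: list[Spot]
    dilution_base: float = 10.0
    spot_volume_ul: float = 3.5
    window: tuple[float, float] = (1, 20)  # open interval of countable plaques

    def __post_init__(self) -> None:
        if self.spot_volume_ul <= 0:
            raise ValueError("spot volume must be positive")
        self.spots = [s if isinstance(s, Spot) else Spot(*s) for s in self.spots]

    @property
    def volume_ml(self) -> float:
        return self.spot_volume_ul / 1000.0

    def qualifying(self) -> list[Spot]:
        lo, hi = self.window
        return [s for s in self.spots if lo < s.count < hi]


@dataclass(frozen=True)
class TiterMeasurement:
    """A titer in PFU/mL on a named host strain."""

    host: str
    titer: UncertainValue
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.titer.value < 0:
            raise ValueError("titer cannot be negative")


def titer_from_spots(series: SpotSeries) -> UncertainValue:
    """Combine a spotting series into one titer (PFU/mL).

    Each countable spot (count strictly inside ``series.window``) gives an
    independent Poisson estimate; estimates are pooled by inverse-variance
    weighting with the Poisson variances evaluated at the common pooled
    titer, which reduces to the unbiased pooled-count estimate
    ``sum(n_i) / sum(1/scale_i)`` (weighting by observed counts instead
    would bias low).  With no countable spot the outcome depends on the series:
    all-zero counts give a flagged "below detection" upper bound at one
    plaque equivalent of the least-diluted spot; an entirely saturated
    series raises (the dilution series was exhausted).
    """
    if not series.spots:
        raise ValueError("empty spot series")
    good = series.qualifying()
    if not good:
        counts = [s.count for s in series.spots]
        if all(c == 0 for c in counts):
            min_exp = min(s.exponent for s in series.spots)
            limit = series.dilution_base**min_exp / series.volume_ml
            return UncertainValue(limit, 0.0, bound="upper", note="below detection")
        if all(c >= series.window[1] for c in counts):
            raise ValueError("dilution series exhausted: every spot saturated")
        raise ValueError("no spot with a count in the countable window "
                         f"{series.window} (counts: {sorted(counts)})")
    total_counts = 0.0
    inv_scale = 0.0
    for s in good:
        scale = series.dilution_base**s.exponent / series.volume_ml
        total_counts += s.count
        inv_scale += 1.0 / scale
    value = total_counts / inv_scale
    return UncertainValue(value, math.sqrt(total_counts) / inv_scale)


def eop(test: TiterMeasurement, reference: TiterMeasurement) -> UncertainValue:
    """Efficiency of plating: test-host titer over reference-host titer.

    A below-detection test titer yields a flagged upper bound on the EOP;
    a below-detection reference is rejected (no meaningful normalization).
    """
    if reference.titer.is_bound:
        raise ValueError("reference titer is a detection bound; EOP undefined")
    if reference.titer.value <= 0:
        raise ValueError("reference titer must be positive")
    out = uv_ratio(test.titer, reference.titer)
    if test.titer.is_bound:
        out = out.flagged("upper bound (test below detection)", bound=test.titer.bound)
    return out


# -- CSV interface ---------------------------------------------------------

def read_spot_csv(path, **series_kwargs) -> dict[tuple[str, str], SpotSeries]:
    """Read a spot-assay table (columns: sample, host, dilution_exponent,
    count, replicate) into one :class:`SpotSeries` per (sample, host)."""
    df = pd.read_csv(path)
    required = {"sample", "host", "dilution_exponent", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spot CSV missing columns: {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    out: dict[tuple[str, str], SpotSeries] = {}
    for (sample, host), grp in df.groupby(["sample", "host"], sort=False):
        spots = [Spot(int(r.dilution_exponent), int(r["count"]), r.replicate)
                 for _, r in grp.iterrows()]
        out[(str(sample), str(host))] = SpotSeries(spots, **series_kwargs)
    return out


def titers_to_frame(titers: dict[tuple[str, str], UncertainValue]) -> pd.DataFrame:
    """Tabulate combined titers as sample/host/titer/sd/flag rows."""
    rows = [
        {"sample": sample, "host": host, "titer": t.value, "sd": t.sd,
         "flag": (t.bound or "") and f"{t.bound} bound: {t.note}"}
        for (sample, host), t in titers.items()
    ]
    return pd.DataFrame(rows, columns=["sample", "host", "titer", "sd", "flag"])
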