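"""Co-speciation calibration points and host divergence date sampling.

A calibration point pairs a named virus clade (a taxon set) with its host's
divergence date, reported in the literature as a median with a 95% interval in
million years (Myr). Dates are sampled from a normal distribution whose mean is
the reported median and whose standard deviation is derived from the wider of
the two interval half-widths::

    sd = max((median - lower95) / 1.96, (upper95 - median) / 1.96)

Draws are truncated to strictly positive times by rejection: the downstream
power-law clock works in log time, and host dates sit well above zero relative
to their uncertainty, so truncation is a rare, minimally distorting event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HostDate",
    "DateDistribution",
    "Clade",
    "CalibrationPoint",
    "make_date_distribution",
    "sample_dates",
    "CALIBRATION_PRESETS",
]

#: z-quantile matching a central 95% normal interval
Z95 = 1.96


@dataclass(frozen=True)
class HostDate:
    """Host divergence date: median and 95% interval bounds, in Myr."""

    median: float
    lower95: float
    upper95: float

    def __post_init__(self) -> None:
        if not self.lower95 <= self.median <= self.upper95:
            raise ValueError(
                f"host date bounds out of order: {self.lower95} <= {self.median} "
                f"<= {self.upper95} violated"
            )
        if self.median <= 0 or self.lower95 < 0:
            raise ValueError("host dates must be positive (Myr before present)")


@dataclass(frozen=True)
class DateDistribution:
    """Normal sampling distribution of a host date (mean, sd in Myr)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class Clade:
    """A named taxon set locating one node per tree via its MRCA."""

    name: str
    taxa: frozenset[str]

    def __init__(self, name: str, taxa: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "taxa", frozenset(taxa))
        if len(self.taxa) < 2:
            raise ValueError(f"clade {name!r} needs >= 2 taxa")


@dataclass(frozen=True)
class CalibrationPoint:
    """A clade whose divergence is tied to a dated host divergence."""

    name: str
    taxa: frozenset[str]
    host_date: HostDate

    def __init__(self, name: str, taxa: Iterable[str], host_date: HostDate):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "taxa", frozenset(taxa))
        object.__setattr__(self, "host_date", host_date)
        if len(self.taxa) < 2:
            raise ValueError(f"calibration point {name!r} needs >= 2 taxa")

    @property
    def clade(self) -> Clade:
        return Clade(self.name, self.taxa)


def make_date_distribution(d: HostDate) -> DateDistribution:
    """Normal (mean, sd) for a host date via the max-of-two-half-widths rule."""
    sd = max((d.median - d.lower95) / Z95, (d.upper95 - d.median) / Z95)
    return DateDistribution(mean=d.median, sd=sd)


def _sample_positive(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal draws truncated to (0, inf) by rejection; constant when sd=0."""
    if sd == 0:
        if mean <= 0:
            raise ValueError(
                f"cannot sample a positive date from mean={mean} with sd=0"
            )
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def sample_dates(
    points: Sequence[CalibrationPoint],
    n_draws: int,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample host dates for each calibration point.

    Returns a DataFrame with one column per point (named after it) and one row
    per draw, in Myr. Draws are independent across points and rows, strictly
    positive, and reproducible for a given seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not points:
        raise ValueError("no calibration points given")
    names = [p.name for p in points]
    if len(set(names)) != len(names):
        raise ValueError("calibration point names must be unique")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cols = {}
    for p in points:
        dist = make_date_distribution(p.host_date)
        cols[p.name] = _sample_positive(rng, dist.mean, dist.sd, n_draws)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Named calibration presets.
#
# The taxon sets name the co-speciation events used for the central-SU
# ("censu-3") and conserved-region ("conserved-5") clocks of SFV dating. Host
# dates are editable placeholders in the style of published primate/eutherian
# timetables; users calibrating real data should substitute the dated host
# intervals they trust, per point, in Myr.
# ---------------------------------------------------------------------------

CALIBRATION_PRESETS: dict[str, list[CalibrationPoint]] = {
    "censu-3": [
        CalibrationPoint(
            "chimp-gorilla SFV split",
            {"SFVptr", "SFVggo"},
            HostDate(8.6, 7.1, 10.1),
        ),
        CalibrationPoint(
            "SFVmcy-SFVmmu split",
            {"SFVmcy", "SFVmmu"},
            HostDate(1.5, 0.9, 2.3),
        ),
        CalibrationPoint(
            "SFV-fereungulata FV split",
            {"SFVptr", "SFVggo", "SFVmcy", "SFVmmu", "BFV", "EFV", "FFV"},
            HostDate(99.0, 78.0, 121.0),
        ),
    ],
    "conserved-5": [
        CalibrationPoint(
            "chimp-gorilla SFV split",
            {"SFVptr", "SFVggo"},
            HostDate(8.6, 7.1, 10.1),
        ),
        CalibrationPoint(
            "SFVppy vs chimp+gorilla SFVs",
            {"SFVppy", "SFVptr", "SFVggo"},
            HostDate(16.5, 13.0, 20.0),
        ),
        CalibrationPoint(
            "SFVmcy-SFVmmu split",
            {"SFVmcy", "SFVmmu"},
            HostDate(1.5, 0.9, 2.3),
        ),
        CalibrationPoint(
            "OWM SFV basal diversification",
            {"SFVmsp", "SFVcae", "SFVcni", "SFVmcy", "SFVmmu"},
            HostDate(11.5, 9.0, 14.5),
        ),
        CalibrationPoint(
            "OWMA SFV basal diversification",
            {"SFVmsp", "SFVcae", "SFVcni", "SFVmcy", "SFVmmu", "SFVptr", "SFVggo", "SFVppy"},
            HostDate(31.56, 25.0, 38.0),
        ),
    ],
}
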