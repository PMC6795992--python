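"""Recombination-hotspot post-processing, alignment splitting, and site rates.

Coordinates are 1-based inclusive alignment columns throughout, matching how
breakpoints and region bounds are reported in recombination-detection output;
gap columns count as columns. Alignments are Biopython
:class:`~Bio.Align.MultipleSeqAlignment` objects read and written as FASTA.

The workflow these functions support: filter per-programme recombination-event
calls down to a consensus set, cluster the surviving breakpoints into hotspot
intervals, split the alignment into the regions between hotspots (optionally
blanking a recombinant segment of a named sequence first), and summarise
site-wise evolutionary rates region by region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSpec",
    "RecombinationEvent",
    "ExcisionRule",
    "read_alignment",
    "write_alignment",
    "consensus_filter",
    "cluster_breakpoints",
    "split_alignment",
    "scale_rates",
    "moving_average",
    "region_rate_summary",
    "rate_ratio",
    "RateRatioResult",
    "read_events_table",
]


@dataclass(frozen=True)
class RegionSpec:
    """A named 1-based inclusive column interval of an alignment."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"region {self.name!r}: need 1 <= start <= end, got "
                f"({self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def columns(self) -> np.ndarray:
        """0-based column indices covered by the region."""
        return np.arange(self.start - 1, self.end)


@dataclass(frozen=True)
class RecombinationEvent:
    """One putative recombination event with per-programme P values."""

    recombinant: str
    start: int
    end: int
    detections: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"event for {self.recombinant!r}: breakpoints out of order"
            )

    def n_supporting(self, alpha: float = 0.05) -> int:
        return sum(1 for p in self.detections.values() if p < alpha)


@dataclass(frozen=True)
class ExcisionRule:
    """Blank one sequence's characters over a full-alignment column range.

    Blanking (gap substitution) rather than column deletion keeps the
    alignment rectangular and preserves column homology for every other
    record; used to drop a recombinant segment of a single sequence.
    """

    seq_id: str
    start: int
    end: int
    region: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"excision for {self.seq_id!r}: range out of order")


def read_alignment(path: str | Path) -> MultipleSeqAlignment:
    return AlignIO.read(str(path), "fasta")


def write_alignment(aln: MultipleSeqAlignment, path: str | Path) -> None:
    AlignIO.write(aln, str(path), "fasta")


def read_events_table(path: str | Path) -> list[RecombinationEvent]:
    """Load events from a delimited table (recombinant, start, end, programme, P).

    Rows sharing (recombinant, start, end) are one event detected by several
    programmes. Comma, tab or whitespace delimited; header required.
    """
    df = pd.read_csv(str(path), sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"recombinant", "start", "end", "programme", "p"}
    if not required <= set(df.columns):
        raise ValueError(
            f"events table must have columns {sorted(required)}, got "
            f"{list(df.columns)}"
        )
    events = []
    for (rec, start, end), grp in df.groupby(
        ["recombinant", "start", "end"], sort=False
    ):
        events.append(
            RecombinationEvent(
                str(rec),
                int(start),
                int(end),
                dict(zip(grp["programme"].astype(str), grp["p"].astype(float))),
            )
        )
    return events


def consensus_filter(
    events: Iterable[RecombinationEvent],
    min_programmes: int = 4,
    alpha: float = 0.05,
) -> list[RecombinationEvent]:
    """Keep events detected by >= ``min_programmes`` programmes at P < ``alpha``.

    The default mirrors the standard consensus rule for multi-programme
    recombination screens: events supported by fewer than four programmes at
    P < 0.05 are discarded.
    """
    return [e for e in events if e.n_supporting(alpha) >= min_programmes]


def cluster_breakpoints(
    breakpoints: Sequence[int], gap: int = 50
) -> list[tuple[int, int]]:
    """Single-linkage 1-D clustering of breakpoint columns.

    Sorted breakpoints at most ``gap`` columns apart join one cluster; each
    cluster is reported as its (min, max) span. This automates the visual
    delimitation of hotspot intervals from a breakpoint map and will generally
    need a dataset-specific ``gap``.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    bps = sorted(int(b) for b in breakpoints)
    if not bps:
        return []
    clusters = [[bps[0], bps[0]]]
    for b in bps[1:]:
        if b - clusters[-1][1] <= gap:
            clusters[-1][1] = b
        else:
            clusters.append([b, b])
    return [(a, b) for a, b in clusters]


def _complement_intervals(
    hotspots: Sequence[RegionSpec], length: int
) -> list[tuple[int, int]]:
    """1-based inclusive intervals covering the columns outside all hotspots."""
    out = []
    pos = 1
    for h in hotspots:
        if h.start > pos:
            out.append((pos, h.start - 1))
        pos = h.end + 1
    if pos <= length:
        out.append((pos, length))
    return out


def split_alignment(
    aln: MultipleSeqAlignment,
    hotspots: Sequence[RegionSpec],
    excisions: Sequence[ExcisionRule] = (),
    region_names: Sequence[str] | None = None,
) -> dict[str, MultipleSeqAlignment]:
    """Split an alignment into the regions between (and excluding) hotspots.

    ``k`` non-overlapping, sorted hotspots produce up to ``k + 1`` region
    alignments covering exactly the columns outside all hotspots, in original
    column order. Excision rules are applied first, replacing the named
    sequence's characters with gaps over full-alignment coordinates.
    """
    L = aln.get_alignment_length()
    for h in hotspots:
        if h.end > L:
            raise ValueError(f"hotspot {h.name!r} extends past column {L}")
    for a, b in zip(hotspots, hotspots[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"hotspots {a.name!r} and {b.name!r} overlap or are unsorted"
            )

    ids = [rec.id for rec in aln]
    seqs = {rec.id: list(str(rec.seq)) for rec in aln}
    for rule in excisions:
        if rule.seq_id not in seqs:
            raise KeyError(f"excision names unknown sequence {rule.seq_id!r}")
        if rule.end > L:
            raise ValueError(f"excision for {rule.seq_id!r} extends past column {L}")
        row = seqs[rule.seq_id]
        for j in range(rule.start - 1, rule.end):
            row[j] = "-"

    intervals = _complement_intervals(hotspots, L)
    if region_names is None:
        region_names = [f"region_{i + 1}" for i in range(len(intervals))]
    if len(region_names) != len(intervals):
        raise ValueError(
            f"{len(intervals)} regions produced but {len(region_names)} names given"
        )
    out: dict[str, MultipleSeqAlignment] = {}
    for name, (start, end) in zip(region_names, intervals):
        records = [
            SeqRecord(
                Seq("".join(seqs[i][start - 1 : end])), id=i, description=""
            )
            for i in ids
        ]
        out[name] = MultipleSeqAlignment(records)
    return out


# -- site-wise evolutionary rates -------------------------------------------


def scale_rates(raw: np.ndarray) -> np.ndarray:
    """Scale site rates so the average over all columns is exactly 1.

    1-D input is one rate per column; 2-D input is (posterior samples x
    columns) and each sample row is scaled independently.
    """
    rates = np.asarray(raw, float)
    if rates.ndim not in (1, 2):
        raise ValueError("rates must be a vector or a samples-by-columns matrix")
    if np.any(rates < 0) or not np.all(np.isfinite(rates)):
        raise ValueError("rates must be finite and >= 0")
    means = rates.mean(axis=-1, keepdims=True)
    if np.any(means == 0):
        raise ValueError("cannot scale an all-zero rate vector")
    return rates / means


def moving_average(rates: np.ndarray, window: int = 10) -> np.ndarray:
    """Centred moving average over ``window`` consecutive site rates.

    Returns ``len(rates) - window + 1`` values (each the plain mean of one
    full window), the conventional smoothing for site-rate profiles.
    """
    rates = np.asarray(rates, float)
    if not 1 <= window <= rates.size:
        raise ValueError("window must be in [1, len(rates)]")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(rates, kernel, mode="valid")


def region_rate_summary(
    rates: np.ndarray, regions: Sequence[RegionSpec]
) -> pd.DataFrame:
    """Arithmetic mean of scaled site rates within each region.

    With a (samples x columns) matrix, each region also gets the median and
    95% HPD of its per-sample means. Raises on regions outside the columns.
    """
    from .dating import hpd_interval

    rates = np.atleast_2d(np.asarray(rates, float))
    L = rates.shape[1]
    rows = []
    for r in regions:
        if r.end > L:
            raise ValueError(f"region {r.name!r} extends past column {L}")
        block = rates[:, r.start - 1 : r.end]
        if block.size == 0:
            raise ValueError(f"region {r.name!r} is empty")
        per_sample = block.mean(axis=1)
        row = {"region": r.name, "mean": float(block.mean())}
        if rates.shape[0] > 1:
            lo, hi = hpd_interval(per_sample)
            row.update(
                median=float(np.median(per_sample)),
                hpd95_lower=lo,
                hpd95_upper=hi,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


@dataclass(frozen=True)
class RateRatioResult:
    """Posterior distribution of a focal/complement mean-rate ratio."""

    ratios: np.ndarray
    mean: float
    hpd_linear: tuple[float, float]
    hpd_log: tuple[float, float]
    n_dropped: int


def rate_ratio(
    rates: np.ndarray,
    focal: RegionSpec,
    complement: Sequence[RegionSpec] | None = None,
) -> RateRatioResult:
    """Per-sample ratio of mean rates: focal region over its complement.

    ``complement`` defaults to every column outside the focal region. Reports
    the mean of the per-sample ratios with 95% HPDs on the linear scale and on
    the (natural) log scale — the log-scale interval is the honest one for a
    multiplicative quantity, the linear one is what rate profiles usually
    print. Samples whose complement mean is 0 are dropped with a warning.
    """
    from .dating import hpd_interval

    rates = np.atleast_2d(np.asarray(rates, float))
    L = rates.shape[1]
    focal_cols = focal.columns()
    if focal_cols[-1] >= L:
        raise ValueError(f"focal region {focal.name!r} extends past column {L}")
    if complement is None:
        comp_mask = np.ones(L, bool)
        comp_mask[focal_cols] = False
        comp_cols = np.nonzero(comp_mask)[0]
    else:
        comp_cols = np.concatenate([r.columns() for r in complement])
        if np.intersect1d(comp_cols, focal_cols).size:
            raise ValueError("focal and complement regions overlap")
    if comp_cols.size == 0:
        raise ValueError("complement is empty")

    f = rates[:, focal_cols].mean(axis=1)
    c = rates[:, comp_cols].mean(axis=1)
    ok = c > 0
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "%d samples dropped from rate ratio (complement mean rate is 0)",
            n_dropped,
        )
    ratios = f[ok] / c[ok]
    if ratios.size == 0:
        raise ValueError("no samples with a positive complement mean rate")
    if ratios.size >= 2:
        lin = hpd_interval(ratios)
        lg = hpd_interval(np.log(ratios))
    else:
        r = float(ratios[0])
        lin, lg = (r, r), (math.log(r), math.log(r))
    return RateRatioResult(
        ratios=ratios,
        mean=float(ratios.mean()),
        hpd_linear=lin,
        hpd_log=lg,
        n_dropped=n_dropped,
    )
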