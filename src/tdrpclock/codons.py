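"""Sense-codon counting and codon-usage contingency testing.

Codon usage is compared between sequence groups (e.g. the two co-circulating
surface-domain variants, and the conserved remainder of the gene) on a fixed
61-row table — the sense codons of the standard genetic code. Stop codons and
triplets containing gaps or ambiguity characters are excluded from the table
but tallied, and zero rows are retained, so a G-group comparison always has
(61 - 1)(G - 1) degrees of freedom. Counts (not frequencies) enter the test:
a chi-square on normalised frequencies would be ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Data import CodonTable
from scipy import stats

from .regions import RegionSpec

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "CodonCountTable",
    "count_codons",
    "codon_chisq",
    "pearson_chisq_statistic",
]

STOP_CODONS: frozenset[str] = frozenset(
    CodonTable.unambiguous_dna_by_id[1].stop_codons
)
#: the 61 sense codons of the standard code, lexicographic order
SENSE_CODONS: list[str] = [
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
]
assert len(SENSE_CODONS) == 61

_VALID = frozenset("ACGT")


def count_codons(
    aln: MultipleSeqAlignment,
    region: RegionSpec,
    frame_offset: int = 0,
    group: str = "group",
) -> tuple[pd.Series, int]:
    """Count sense codons in one alignment region, pooled over sequences.

    Non-overlapping triplets are read from ``region.start + frame_offset``
    onwards. Triplets containing a gap or ambiguity character, and stop
    codons, go to the discard tally; a trailing partial triplet is dropped
    silently. Returns (61-codon count Series named ``group``, discard count).
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    L = aln.get_alignment_length()
    if region.end > L:
        raise ValueError(f"region {region.name!r} extends past column {L}")
    counts = dict.fromkeys(SENSE_CODONS, 0)
    discarded = 0
    for rec in aln:
        seq = str(rec.seq)[region.start - 1 + frame_offset : region.end].upper()
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if set(codon) <= _VALID and codon not in STOP_CODONS:
                counts[codon] += 1
            else:
                discarded += 1
    return pd.Series(counts, name=group, dtype=int), discarded


@dataclass
class CodonCountTable:
    """61 sense codons x groups count matrix, with per-group discard tallies."""

    counts: pd.DataFrame
    discards: pd.Series

    @classmethod
    def from_groups(
        cls,
        aln_by_group: Mapping[str, tuple[MultipleSeqAlignment, Sequence[RegionSpec]]],
        frame_offset: int = 0,
    ) -> "CodonCountTable":
        """Build a table from per-group (alignment, regions) pairs.

        A group's counts pool its regions (each read in frame from its own
        start plus ``frame_offset``).
        """
        cols, disc = {}, {}
        for group, (aln, regions) in aln_by_group.items():
            total = pd.Series(0, index=SENSE_CODONS, dtype=int)
            d = 0
            for region in regions:
                c, dd = count_codons(aln, region, frame_offset, group)
                total += c
                d += dd
            cols[group] = total
            disc[group] = d
        return cls(pd.DataFrame(cols), pd.Series(disc, dtype=int))

    @property
    def groups(self) -> list[str]:
        return list(self.counts.columns)


def pearson_chisq_statistic(observed: np.ndarray) -> float:
    """Pearson chi-square statistic with margin-derived expected counts.

    Rows whose total is zero contribute 0 (their expected counts are zero in
    every cell) and are not dropped. No continuity correction.
    """
    obs = np.asarray(observed, float)
    if obs.ndim != 2:
        raise ValueError("observed must be a 2-D table")
    if np.any(obs < 0):
        raise ValueError("counts must be >= 0")
    grand = obs.sum()
    if grand <= 0:
        raise ValueError("grand total must be positive")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / grand
    keep = expected > 0
    return float((((obs - expected) ** 2)[keep] / expected[keep]).sum())


def codon_chisq(table: CodonCountTable) -> tuple[float, int, float]:
    """Chi-square comparison of codon usage across groups.

    Returns ``(statistic, df, p)`` where ``df = (61 - 1)(G - 1)`` — the full
    sense-codon table, zero rows retained — and ``p`` is the upper tail of the
    chi-square distribution.
    """
    obs = table.counts.to_numpy(float)
    n_groups = obs.shape[1]
    if n_groups < 2:
        raise ValueError("need >= 2 groups to compare codon usage")
    zero_groups = [g for g, tot in table.counts.sum().items() if tot == 0]
    if zero_groups:
        raise ValueError(f"groups with zero codon counts: {zero_groups}")
    stat = pearson_chisq_statistic(obs)
    df = (len(SENSE_CODONS) - 1) * (n_groups - 1)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p
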