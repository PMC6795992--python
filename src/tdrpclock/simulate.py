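"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the shape of a real co-speciation dating study:

* posterior samples of ultrametric trees whose internal-node heights follow
  the power-law clock ``t = exp(alpha + beta ln s)`` inverted, perturbed by
  multiplicative lognormal noise (heights stay positive and the noise is
  symmetric on the log scale where the clock lives);
* region-structured nucleotide alignments simulated region-by-region down
  different trees under a one-parameter equal-rates substitution model,
  emulating a central module with its own evolutionary history;
* site-rate matrices with region-elevated means, scaled to global mean 1;
* recombination-event tables with hotspot-concentrated consensus events and
  weakly supported noise events.

All generators are pure functions of their arguments and a seed. The shipped
demo geometry mirrors the study design this package targets: calibration
nodes at ~8.6, ~5.3 and ~100 Myr, shallow target clades at ~0.4-1.7 Myr, and
a deep two-variant split at ~29.9 Myr.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calibration import (
    CalibrationPoint,
    Clade,
    HostDate,
    make_date_distribution,
    _sample_positive,
)
from .dating import TdrpDatingModel
from .regions import RecombinationEvent, RegionSpec
from .trees import PhyloTree, PosteriorTreeSet, normalize_label

__all__ = [
    "SimSpec",
    "SimTruth",
    "simulate_posterior_trees",
    "simulate_region_alignment",
    "simulate_rate_matrix",
    "simulate_recombination_events",
    "hpd_coverage_experiment",
    "demo_host_tree",
    "demo_sim_spec",
    "demo_calibrations",
    "demo_targets",
]

def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimSpec:
    """Ground truth for a synthetic posterior tree sample.

    ``host_tree`` is an ultrametric tree whose node heights are true node
    times in Myr; ``alpha``/``beta`` are the true clock parameters (natural
    logs, t in Myr); ``sigma`` is the lognormal sd of multiplicative
    node-height noise; ``n_trees`` is the number of posterior draws.
    """

    host_tree: PhyloTree
    alpha: float
    beta: float
    sigma: float
    n_trees: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_trees < 2:
            raise ValueError("n_trees must be >= 2")
        if self.beta == 0:
            raise ValueError("beta must be non-zero")


@dataclass(frozen=True)
class SimTruth:
    """True per-clade times (Myr) and heights (s-units), plus (alpha, beta)."""

    alpha: float
    beta: float
    table: pd.DataFrame  # one row per internal node: clade, time_Myr, height_s

    def _lookup(self, taxa) -> pd.Series:
        key = frozenset(normalize_label(t) for t in taxa)
        for _, row in self.table.iterrows():
            if row["clade"] == key:
                return row
        raise KeyError(f"no internal node with clade {sorted(key)}")

    def true_time(self, taxa) -> float:
        return float(self._lookup(taxa)["time_Myr"])

    def true_height(self, taxa) -> float:
        return float(self._lookup(taxa)["height_s"])


def _true_heights(spec: SimSpec) -> tuple[np.ndarray, np.ndarray]:
    """(times, heights) per node; tips have time 0 and height 0."""
    host = spec.host_tree
    times = np.array(host.node_heights())
    heights = np.zeros_like(times)
    for i in host.internal_nodes():
        if times[i] <= 0:
            raise ValueError(f"internal node {i} has non-positive time {times[i]}")
        h = math.exp((math.log(times[i]) - spec.alpha) / spec.beta)
        if not math.isfinite(h) or h <= 0:
            raise ValueError(
                f"alpha={spec.alpha}, beta={spec.beta} give a non-finite height "
                f"at t={times[i]}"
            )
        heights[i] = h
    return times, heights


def _truncated_lognormal_factor(rng, sigma: float, log_upper: float) -> float:
    """exp(sigma * Z) with Z standard normal truncated to sigma*Z < log_upper."""
    b = log_upper / sigma
    mass = ndtr(b)
    u = rng.random()
    if mass <= 1e-300:  # bound far in the lower tail; sample at the bound
        return math.exp(log_upper - sigma * 1e-8)
    return math.exp(sigma * ndtri(u * mass))


def simulate_posterior_trees(
    spec: SimSpec, seed=0
) -> tuple[PosteriorTreeSet, SimTruth]:
    """Draw a posterior-style tree sample around the true clock heights.

    Each draw multiplies every internal node's true height by an independent
    lognormal(0, sigma) factor; parent-above-child ordering is enforced by
    conditioning each non-root node's factor below its parent's drawn height
    (exact truncated sampling, equivalent to redrawing violations). Branch
    lengths are rebuilt from the noisy heights, so every tree is exactly
    ultrametric.
    """
    rng = _as_generator(seed)
    host = spec.host_tree
    times, s_true = _true_heights(spec)
    internal = host.internal_nodes()
    parent = host.parent
    trees = []
    for _ in range(spec.n_trees):
        h = np.zeros_like(s_true)
        if spec.sigma == 0:
            h[internal] = s_true[internal]
        else:
            for i in internal:  # preorder: parents already final
                if parent[i] == -1:
                    h[i] = s_true[i] * math.exp(
                        spec.sigma * rng.standard_normal()
                    )
                else:
                    h[i] = s_true[i] * _truncated_lognormal_factor(
                        rng, spec.sigma, math.log(h[parent[i]] / s_true[i])
                    )
        trees.append(host.with_heights(h))
    table = pd.DataFrame(
        {
            "clade": [
                frozenset(
                    normalize_label(host.labels[j])
                    for j in host.tip_order
                    if host._mask[j] & host._mask[i]
                )
                for i in internal
            ],
            "time_Myr": times[internal],
            "height_s": s_true[internal],
        }
    )
    return (
        PosteriorTreeSet(trees, burn_in_fraction=0.0, source_path="<simulated>"),
        SimTruth(spec.alpha, spec.beta, table),
    )


# -- sequence simulation ------------------------------------------------------

_P_SAME = 0.25


def jc69_difference_probability(branch_length: float) -> float:
    """Expected proportion of differing sites across one branch (JC69)."""
    return 0.75 * (1.0 - math.exp(-4.0 * branch_length / 3.0))


def _simulate_jc69(tree: PhyloTree, length: int, rng) -> dict[str, np.ndarray]:
    """Simulate one region down a tree; returns tip label -> base indices."""
    seqs: dict[int, np.ndarray] = {}
    seqs[tree.root] = rng.integers(0, 4, size=length)
    for i in range(1, tree.n_nodes):
        parent_seq = seqs[tree.parent[i]]
        p = jc69_difference_probability(tree.length[i])
        child = parent_seq.copy()
        hit = rng.random(length) < p
        n_hit = int(hit.sum())
        if n_hit:
            child[hit] = (child[hit] + rng.integers(1, 4, size=n_hit)) % 4
        seqs[i] = child
    return {tree.labels[i]: seqs[i] for i in tree.tip_order}


_BASES = np.array(list("ACGT"))


def simulate_region_alignment(
    segments: Sequence[tuple[str, int, PhyloTree | None]],
    seed=0,
) -> tuple[MultipleSeqAlignment, list[RegionSpec]]:
    """Concatenate independently simulated regions into one alignment.

    ``segments`` is an ordered list of ``(name, length, tree)``; each region
    with a tree is simulated down that tree under the equal-rates
    one-parameter (JC69) model, and a ``None`` tree marks filler columns
    (e.g. a recombination hotspot) drawn iid uniform per sequence, carrying no
    shared history. All trees must share one tip set. Returns the alignment
    and the true region boundaries in 1-based coordinates.
    """
    rng = _as_generator(seed)
    trees = [t for _, _, t in segments if t is not None]
    if not trees:
        raise ValueError("at least one segment needs a tree")
    tip_labels = trees[0].tip_labels
    ref = trees[0].tip_label_set()
    for t in trees[1:]:
        if t.tip_label_set() != ref:
            raise ValueError("all segment trees must share one tip set")
    for name, length, _ in segments:
        if length < 1:
            raise ValueError(f"segment {name!r} has non-positive length")

    parts: dict[str, list[np.ndarray]] = {lab: [] for lab in tip_labels}
    specs = []
    pos = 1
    for name, length, tree in segments:
        if tree is None:
            for lab in tip_labels:
                parts[lab].append(rng.integers(0, 4, size=length))
        else:
            tip_seqs = {
                normalize_label(k): v
                for k, v in _simulate_jc69(tree, length, rng).items()
            }
            for lab in tip_labels:
                parts[lab].append(tip_seqs[normalize_label(lab)])
        specs.append(RegionSpec(name, pos, pos + length - 1))
        pos += length
    records = [
        SeqRecord(
            Seq("".join(_BASES[np.concatenate(parts[lab])])),
            id=lab.replace(" ", "_"),
            description="",
        )
        for lab in tip_labels
    ]
    return MultipleSeqAlignment(records), specs


def simulate_rate_matrix(
    L: int,
    region_means: Sequence[tuple[RegionSpec, float]],
    n_samples: int = 1,
    noise_sd: float = 0.0,
    seed=0,
) -> tuple[np.ndarray, dict[str, float]]:
    """Site-rate samples with region-structured means, scaled to mean 1.

    Each column's raw rate is gamma-distributed with its region's mean and
    ``noise_sd`` (a point mass when ``noise_sd`` is 0); columns covered by no
    region default to mean 1. Each sample row is then rescaled to average 1.
    Returns the (n_samples x L) scaled matrix and the configured true means.
    """
    from .regions import scale_rates

    rng = _as_generator(seed)
    means = np.ones(L)
    covered = np.zeros(L, bool)
    for r, m in region_means:
        if m <= 0:
            raise ValueError(f"region {r.name!r} mean must be > 0")
        if r.end > L:
            raise ValueError(f"region {r.name!r} extends past column {L}")
        if covered[r.columns()].any():
            raise ValueError(f"region {r.name!r} overlaps another region")
        covered[r.columns()] = True
        means[r.columns()] = m
    if noise_sd == 0:
        raw = np.tile(means, (n_samples, 1))
    else:
        shape = (means / noise_sd) ** 2
        scale = noise_sd**2 / means
        raw = rng.gamma(shape, scale, size=(n_samples, L))
    return scale_rates(raw), {r.name: m for r, m in region_means}


def simulate_recombination_events(
    hotspots: Sequence[RegionSpec],
    n_consensus: int = 5,
    n_spurious: int = 3,
    alignment_length: int = 2883,
    programmes: Sequence[str] = (
        "RDP",
        "GENECONV",
        "Chimaera",
        "MaxChi",
        "BootScan",
        "SiScan",
        "3Seq",
    ),
    seed=0,
) -> list[RecombinationEvent]:
    """Event table with hotspot-bounded consensus events plus weak noise.

    Consensus events have both breakpoints inside the two flanking hotspots
    and are detected by all programmes at P < 0.05; spurious events fall
    anywhere and are supported by fewer than four programmes, so a
    four-programme consensus filter removes exactly the spurious ones.
    """
    if len(hotspots) != 2:
        raise ValueError("expected exactly two flanking hotspots")
    rng = _as_generator(seed)
    h1, h2 = hotspots
    events = []
    for k in range(n_consensus):
        events.append(
            RecombinationEvent(
                f"recombinant_{k + 1}",
                int(rng.integers(h1.start, h1.end + 1)),
                int(rng.integers(h2.start, h2.end + 1)),
                {p: float(rng.uniform(1e-8, 0.049)) for p in programmes},
            )
        )
    for k in range(n_spurious):
        a, b = np.sort(rng.integers(1, alignment_length + 1, size=2))
        n_sig = int(rng.integers(1, 4))
        sig = list(rng.choice(len(programmes), size=n_sig, replace=False))
        detections = {
            p: float(rng.uniform(1e-4, 0.049))
            if i in sig
            else float(rng.uniform(0.05, 0.9))
            for i, p in enumerate(programmes)
        }
        events.append(
            RecombinationEvent(f"spurious_{k + 1}", int(a), max(int(b), int(a)), detections)
        )
    return events


# -- demo geometry ------------------------------------------------------------

DEMO_ALPHA = 4.114
DEMO_BETA = 1.762
DEMO_SIGMA = 0.1
DEMO_N_TREES = 500

_DEMO_NEWICK = (
    "((FFV:60,(BFV:30,EFV:30):30):40,"
    "(((SFVggo_I:8.6,SFVptr_I:8.6):6.4,"
    "(SFVmspN_I:1.075,SFVmspS_I:1.075):13.925):14.892,"
    "((SFVmcy_II:5.3,SFVmmu_II:5.3):9.7,"
    "(SFVmspN_II:0.415,SFVmspS_II:0.415):14.585):14.892):70.108);"
)

_DEMO_SFV_TAXA = (
    "SFVggo_I",
    "SFVptr_I",
    "SFVmspN_I",
    "SFVmspS_I",
    "SFVmcy_II",
    "SFVmmu_II",
    "SFVmspN_II",
    "SFVmspS_II",
)


def demo_host_tree() -> PhyloTree:
    """Host/virus demo topology with node heights in Myr.

    Eleven tips: three fereungulata viruses (split from the simian clade at
    100 Myr) and two virus variants, each holding a dated ape or monkey split
    (8.6 and 5.3 Myr) and a shallow mandrill North/South split (1.075 and
    0.415 Myr); the two variants diverge at 29.892 Myr.
    """
    return PhyloTree.from_newick(_DEMO_NEWICK)


def demo_sim_spec(
    sigma: float = DEMO_SIGMA, n_trees: int = DEMO_N_TREES
) -> SimSpec:
    return SimSpec(demo_host_tree(), DEMO_ALPHA, DEMO_BETA, sigma, n_trees)


def demo_calibrations(
    sd_zero: bool = False,
) -> list[CalibrationPoint]:
    """Three calibration points at the demo tree's dated host splits.

    Bounds are +/- ~20% of the median (1.96 sd ~ 10% coefficient of
    variation), the scale of published host timetable intervals. With
    ``sd_zero`` the dates are exact, for noiseless recovery checks.
    """

    def hd(m, lo, hi):
        return HostDate(m, m, m) if sd_zero else HostDate(m, lo, hi)

    return [
        CalibrationPoint(
            "chimp-gorilla split", {"SFVggo_I", "SFVptr_I"}, hd(8.6, 6.9, 10.3)
        ),
        CalibrationPoint(
            "mcy-mmu split", {"SFVmcy_II", "SFVmmu_II"}, hd(5.3, 4.2, 6.4)
        ),
        CalibrationPoint(
            "SFV-fereungulata split",
            set(_DEMO_SFV_TAXA) | {"FFV", "BFV", "EFV"},
            hd(100.0, 80.0, 120.0),
        ),
    ]


def demo_targets() -> list[Clade]:
    return [
        Clade("mandrill N-S split (variant I)", {"SFVmspN_I", "SFVmspS_I"}),
        Clade("mandrill N-S split (variant II)", {"SFVmspN_II", "SFVmspS_II"}),
        Clade("env variant origin", set(_DEMO_SFV_TAXA)),
    ]


# -- calibration-coverage experiment -----------------------------------------


def hpd_coverage_experiment(
    host_tree: PhyloTree,
    alpha: float,
    beta: float,
    sigma: float,
    calibrations: Sequence[CalibrationPoint],
    target: Clade,
    n_trees: int = 500,
    n_replicates: int = 200,
    seed: int = 0,
    max_redraws: int = 100,
) -> pd.DataFrame:
    """Frequentist calibration of the pooled 95% HPD on a target time.

    Each replicate is a full synthetic study drawn from the model the clock
    assumes, so the nominal 95% interval should cover ~95% of replicates:

    1. true calibration dates are drawn from their (truncated) normal date
       distributions and written into the host tree (the target's true time
       is untouched);
    2. a single "observed" height vector is drawn around the true heights
       with lognormal(0, sigma) noise — the analogue of the data — and the
       posterior tree sample is then simulated around those observed heights
       with the same sigma, emulating a posterior whose spread matches the
       data error;
    3. the clock is fitted as in a real analysis (date draws from the
       published distributions) and coverage of the true target time by the
       pooled 95% HPD is recorded.

    Returns one row per replicate with the estimate, interval, and coverage
    flag; ``df["covered"].mean()`` is the empirical coverage.
    """
    ss = np.random.SeedSequence(seed)
    host = host_tree
    truth_time = host.clade_height(target.taxa)
    calib_nodes = [host.mrca(p.taxa) for p in calibrations]
    dists = [make_date_distribution(p.host_date) for p in calibrations]
    base_times = np.array(host.node_heights())
    rows = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        # 1. replicate truth: calibration dates from their priors
        for _ in range(max_redraws):
            times = base_times.copy()
            for node, dist in zip(calib_nodes, dists):
                times[node] = _sample_positive(rng, dist.mean, dist.sd, 1)[0]
            try:
                host_truth = host.with_heights(times)
                break
            except ValueError:  # parent/child ordering violated; redraw
                continue
        else:
            raise RuntimeError("could not draw ordered calibration dates")
        # 2. one observed height vector, then a posterior sample around it
        obs_set, _ = simulate_posterior_trees(
            SimSpec(host_truth, alpha, beta, sigma, 2), rng
        )
        observed = np.array(obs_set[0].node_heights())
        pseudo_times = np.zeros_like(observed)
        for i in host.internal_nodes():
            pseudo_times[i] = math.exp(alpha + beta * math.log(observed[i]))
        host_centered = host.with_heights(pseudo_times)
        tree_set, _ = simulate_posterior_trees(
            SimSpec(host_centered, alpha, beta, sigma, n_trees), rng
        )
        # 3. standard analysis against the published date distributions
        res = TdrpDatingModel(tree_set, calibrations, [target]).fit(
            child.spawn(1)[0]
        )
        est = res.time_estimates[0]
        rows.append(
            {
                "replicate": rep,
                "true_time": truth_time,
                "median": est.median,
                "hpd_lower": est.hpd_lower,
                "hpd_upper": est.hpd_upper,
                "covered": est.hpd_lower <= truth_time <= est.hpd_upper,
            }
        )
    return pd.DataFrame(rows)
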