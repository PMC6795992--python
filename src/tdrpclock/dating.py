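"""The power-law time-dependent-rate (TDRP) clock, fitted per posterior tree.

Measured viral evolutionary rates decay with the timescale over which they are
measured. For node ages this is captured by a power law linking a node's age
``t`` (Myr) to its height ``s`` (expected substitutions/site per lineage)::

    log t = alpha + beta * log s

Given a posterior sample of trees with substitutions/site branch lengths and a
set of calibration clades with dated host divergences, the clock is calibrated
separately in every posterior tree: the calibration nodes' heights are
extracted, one host date is drawn per calibration point from its normal date
distribution, an unweighted least-squares line is fitted in log-log space, and
the fitted line converts the heights of any target clades in that same tree
into times. Pooling over trees propagates phylogenetic and calibration-date
uncertainty jointly; pooled distributions are summarised by their median and
95% highest-posterior-density (HPD) interval.

Logs are natural and time is in Myr by convention. Predictions are invariant
to the log base (``beta`` is base-invariant and ``alpha`` transforms
consistently), so the choice only affects how ``alpha`` reads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationPoint, Clade, sample_dates
from .trees import PosteriorTreeSet

logger = logging.getLogger(__name__)

__all__ = [
    "fit_power_law",
    "fit_tdrp_draw",
    "predict_time",
    "hpd_interval",
    "TimeEstimate",
    "TdrpDatingModel",
    "TdrpDatingResults",
    "run_dating",
    "report_table",
]

_LOG = {"natural": np.log, "base10": np.log10}
_EXP = {"natural": np.exp, "base10": lambda x: np.power(10.0, x)}


class SingularFitError(ValueError):
    """All calibration heights coincide; the log-log line is undetermined."""


def fit_power_law(
    s: Sequence[float], t: Sequence[float], log_base: str = "natural"
) -> tuple[float, float]:
    """Fit ``log t = alpha + beta log s`` by unweighted least squares.

    With exactly two (distinct) points this is exact interpolation. Raises
    :class:`SingularFitError` if all ``s`` coincide and :class:`ValueError`
    for non-positive inputs or fewer than two points.
    """
    s = np.asarray(s, float)
    t = np.asarray(t, float)
    if s.size != t.size or s.size < 2:
        raise ValueError("need >= 2 (s, t) pairs")
    if not (np.all(s > 0) and np.all(t > 0)):
        raise ValueError("all s and t must be strictly positive")
    if log_base not in _LOG:
        raise ValueError(f"unknown log base {log_base!r}")
    x = _LOG[log_base](s)
    y = _LOG[log_base](t)
    xm = x.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise SingularFitError("all calibration heights are identical")
    ym = y.mean()
    beta = float(((x - xm) * (y - ym)).sum()) / sxx
    alpha = float(ym - beta * xm)
    return alpha, beta


#: alias matching the per-draw role the fit plays inside the model
fit_tdrp_draw = fit_power_law


def predict_time(
    alpha: float, beta: float, s: float | np.ndarray, log_base: str = "natural"
) -> float | np.ndarray:
    """Convert node height(s) ``s`` to time via ``t = exp(alpha + beta log s)``."""
    s = np.asarray(s, float)
    if np.any(s <= 0):
        raise ValueError("node height s must be strictly positive")
    out = _EXP[log_base](alpha + beta * _LOG[log_base](s))
    return float(out) if out.ndim == 0 else out


def hpd_interval(
    samples: Sequence[float], mass: float = 0.95
) -> tuple[float, float]:
    """Shortest contiguous interval of sorted samples holding >= ``mass``.

    The interval spans ``ceil(mass * n)`` consecutive order statistics; among
    equally short windows the leftmost is returned (Tracer-style HPD).
    """
    x = np.sort(np.asarray(samples, float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 samples for an HPD interval")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    m = int(math.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass(frozen=True)
class TimeEstimate:
    """Pooled time distribution for one target clade, in Myr."""

    name: str
    draws: np.ndarray
    median: float
    hpd_lower: float
    hpd_upper: float

    @classmethod
    def from_draws(cls, name: str, draws: np.ndarray, mass: float = 0.95):
        lo, hi = hpd_interval(draws, mass)
        return cls(name, draws, float(np.median(draws)), lo, hi)


class TdrpDatingModel:
    """Per-tree power-law clock calibration over a posterior tree sample.

    Parameters
    ----------
    tree_set
        Post-burn-in posterior trees with substitutions/site branch lengths.
    calibrations
        Calibration points (>= 2, with >= 2 distinct heights per tree).
    targets
        Clades whose divergence times are to be estimated.
    log_base
        ``"natural"`` (default) or ``"base10"``; affects only how ``alpha``
        reads, never the predicted times.
    max_skip_fraction
        Trees in which a calibration clade has non-positive height are skipped
        with a warning; above this fraction of skipped trees the fit aborts.
    """

    def __init__(
        self,
        tree_set: PosteriorTreeSet,
        calibrations: Sequence[CalibrationPoint],
        targets: Sequence[Clade],
        log_base: str = "natural",
        max_skip_fraction: float = 0.2,
    ):
        if len(calibrations) < 2:
            raise ValueError("need >= 2 calibration points")
        if not targets:
            raise ValueError("need >= 1 target clade")
        names = [c.name for c in calibrations] + [t.name for t in targets]
        if len(set(names)) != len(names):
            raise ValueError("calibration/target names must be unique")
        if log_base not in _LOG:
            raise ValueError(f"unknown log base {log_base!r}")
        # fail early on unresolvable taxa (checked against the first tree;
        # the tree set guarantees a shared tip set)
        tree0 = tree_set[0]
        for clade in list(calibrations) + list(targets):
            tree0.mrca(clade.taxa)
        self.tree_set = tree_set
        self.calibrations = list(calibrations)
        self.targets = list(targets)
        self.log_base = log_base
        self.max_skip_fraction = max_skip_fraction

    def fit(self, seed: int | np.random.SeedSequence = 0) -> "TdrpDatingResults":
        """Calibrate the clock in every tree and pool the target times.

        One fresh host-date draw is made per calibration point per tree, so
        date and tree uncertainty propagate jointly. All randomness descends
        from ``seed``.
        """
        n = len(self.tree_set)
        dates = sample_dates(self.calibrations, n, seed)
        date_arr = dates.to_numpy()
        rows = []
        skipped = []
        mono_counts = {c.name: 0 for c in self.calibrations + self.targets}
        for k, tree in enumerate(self.tree_set):
            s_cal = np.array(
                [tree.clade_height(c.taxa) for c in self.calibrations]
            )
            for c in self.calibrations + self.targets:
                if tree.is_monophyletic(c.taxa):
                    mono_counts[c.name] += 1
            if np.any(s_cal <= 0):
                skipped.append(k)
                continue
            alpha, beta = fit_power_law(s_cal, date_arr[k], self.log_base)
            s_tgt = np.array([tree.clade_height(t.taxa) for t in self.targets])
            if np.any(s_tgt <= 0):
                skipped.append(k)
                continue
            t_tgt = predict_time(alpha, beta, s_tgt, self.log_base)
            rows.append((k, alpha, beta, *np.atleast_1d(t_tgt)))
        if skipped:
            logger.warning(
                "%d/%d trees skipped (calibration or target clade with "
                "non-positive height)",
                len(skipped),
                n,
            )
        if len(skipped) > self.max_skip_fraction * n:
            raise RuntimeError(
                f"{len(skipped)}/{n} trees skipped, above the "
                f"{self.max_skip_fraction:.0%} tolerance"
            )
        draws = pd.DataFrame(
            rows,
            columns=["tree_index", "alpha", "beta"]
            + [f"t_{t.name}" for t in self.targets],
        )
        monophyly = pd.Series(
            {k: v / n for k, v in mono_counts.items()}, name="fraction_monophyletic"
        )
        return TdrpDatingResults(self, draws, skipped, monophyly)


class TdrpDatingResults:
    """Pooled clock draws and per-target time estimates with 95% HPDs."""

    def __init__(
        self,
        model: TdrpDatingModel,
        draws: pd.DataFrame,
        skipped: list[int],
        monophyly: pd.Series,
    ):
        self.model = model
        self.draws = draws
        self.skipped_trees = skipped
        self.monophyly = monophyly
        self.log_base = model.log_base
        self.alpha = float(draws["alpha"].median())
        self.beta = float(draws["beta"].median())
        self.alpha_hpd = hpd_interval(draws["alpha"])
        self.beta_hpd = hpd_interval(draws["beta"])
        self.time_estimates = [
            TimeEstimate.from_draws(t.name, draws[f"t_{t.name}"].to_numpy())
            for t in model.targets
        ]

    @property
    def n_trees_used(self) -> int:
        return len(self.draws)

    def report_table(self) -> pd.DataFrame:
        """One row per target clade: median and 95% HPD bounds, in Myr."""
        return pd.DataFrame(
            {
                "clade": [e.name for e in self.time_estimates],
                "median_Myr": [e.median for e in self.time_estimates],
                "hpd95_lower_Myr": [e.hpd_lower for e in self.time_estimates],
                "hpd95_upper_Myr": [e.hpd_upper for e in self.time_estimates],
            }
        ).set_index("clade")

    def summary(self) -> str:
        """Human-readable report: clock parameters, then the target table."""
        lines = [
            "Power-law TDRP clock: log t = alpha + beta log s "
            f"({self.log_base} logs, t in Myr)",
            f"  trees used: {self.n_trees_used}"
            + (f" ({len(self.skipped_trees)} skipped)" if self.skipped_trees else ""),
            f"  alpha: {self.alpha:.3f}  (95% HPD {self.alpha_hpd[0]:.3f} - "
            f"{self.alpha_hpd[1]:.3f})",
            f"  beta:  {self.beta:.3f}  (95% HPD {self.beta_hpd[0]:.3f} - "
            f"{self.beta_hpd[1]:.3f})",
            "",
            self.report_table().to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        non_mono = self.monophyly[self.monophyly < 1.0]
        if len(non_mono):
            lines += [
                "",
                "Clades not monophyletic in every tree "
                "(MRCA used regardless):",
                non_mono.to_string(float_format=lambda v: f"{v:.3f}"),
            ]
        return "\n".join(lines)

    def plot_timescale(self, ax=None):
        """Median + HPD error bars per target clade (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.report_table()
        y = np.arange(len(tab))
        med = tab["median_Myr"].to_numpy()
        err = np.vstack(
            [med - tab["hpd95_lower_Myr"], tab["hpd95_upper_Myr"] - med]
        )
        ax.errorbar(med, y, xerr=np.maximum(err, 0), fmt="o", capsize=3)
        ax.set_yticks(y, tab.index)
        ax.set_xlabel("divergence time (Myr)")
        return ax


def run_dating(
    trees: PosteriorTreeSet,
    calibrations: Sequence[CalibrationPoint],
    targets: Sequence[Clade],
    seed: int = 0,
    log_base: str = "natural",
) -> TdrpDatingResults:
    """Convenience wrapper: build a :class:`TdrpDatingModel` and fit it."""
    return TdrpDatingModel(trees, calibrations, targets, log_base=log_base).fit(seed)


def report_table(results: TdrpDatingResults) -> pd.DataFrame:
    """Functional alias for :meth:`TdrpDatingResults.report_table`."""
    return results.report_table()
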