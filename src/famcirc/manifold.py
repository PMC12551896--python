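"""Neural-manifold distance metrics over fixed-point representations.

Each stimulus representation is the converged excitatory steady state r*.
For a sample k of target l at noise level n, three Euclidean distances
characterize the local manifold geometry:

* level distance D_lev: mean distance to the samples of the same target at
  the adjacent lower noise level (the clean target is the single level-0
  sample);
* residual distance D_res: mean distance to the other samples at the same
  (target, level);
* signal distance D_sig: mean distance to the samples of the *other* targets
  at the same noise level.

The relative distances R_lev = D_lev/D_sig and R_res = D_res/D_sig quantify
the size of a target's variants manifold relative to the concept manifold;
their decrease during familiarity training is manifold compression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FixedPointTable",
    "level_distance",
    "residual_distance",
    "signal_distance",
    "relative_distances",
    "manifold_objective",
    "compression_vs_familiarity_correlation",
]


@dataclass
class FixedPointTable:
    """Map (noise_level, target_id, sample_index) -> steady-state r_e vector.

    Level 0.0 with sample 0 holds the clean target.  ``epoch`` labels the
    probe the table was recorded at.
    """

    data: dict = field(default_factory=dict)
    epoch: int = -1

    def add(self, level: float, target: int, sample: int, r_star: np.ndarray):
        self.data[(float(level), int(target), int(sample))] = np.asarray(
            r_star, dtype=float
        )

    def __len__(self):
        return len(self.data)

    def __getitem__(self, key):
        return self.data[key]

    @property
    def levels(self) -> list[float]:
        return sorted({k[0] for k in self.data})

    @property
    def targets(self) -> list[int]:
        return sorted({k[1] for k in self.data})

    def samples_at(self, level: float, target: int) -> list[int]:
        return sorted(k[2] for k in self.data if k[0] == level and k[1] == target)

    def lower_level(self, level: float) -> float:
        lv = self.levels
        i = lv.index(level)
        if i == 0:
            raise KeyError(f"level {level} has no lower neighbor")
        return lv[i - 1]

    @classmethod
    def from_records(cls, records, epoch: int = -1) -> "FixedPointTable":
        """Build from FixedPointRecord objects carrying (level, target, sample)."""
        t = cls(epoch=epoch)
        for rec in records:
            t.add(rec.noise_level, rec.target_id, rec.sample_index, rec.r_star)
        return t


def _dist(a, b):
    return float(np.linalg.norm(a - b))


def level_distance(table: FixedPointTable, level: float, target: int,
                   sample: int) -> float:
    """Mean distance to same-target samples at the adjacent lower noise level."""
    lower = table.lower_level(level)
    r = table[(level, target, sample)]
    peers = table.samples_at(lower, target)
    if not peers:
        raise KeyError(f"no samples at level {lower} for target {target}")
    return float(
        np.mean([_dist(r, table[(lower, target, k)]) for k in peers])
    )


def residual_distance(table: FixedPointTable, level: float, target: int,
                      sample: int) -> float:
    """Mean distance to the other samples at the same (level, target); NaN if alone."""
    r = table[(level, target, sample)]
    peers = [k for k in table.samples_at(level, target) if k != sample]
    if not peers:
        return float("nan")
    return float(np.mean([_dist(r, table[(level, target, k)]) for k in peers]))


def signal_distance(table: FixedPointTable, level: float, target: int,
                    sample: int) -> float:
    """Mean distance to other targets' samples at the same level; NaN if single-target."""
    r = table[(level, target, sample)]
    others = [
        key for key in table.data
        if key[0] == level and key[1] != target
    ]
    if not others:
        return float("nan")
    return float(np.mean([_dist(r, table[key]) for key in others]))


def relative_distances(table: FixedPointTable) -> pd.DataFrame:
    """Per-(level, target, sample) distance table for all noisy levels.

    Columns: level, target, sample, D_lev, D_res, D_sig, R_lev, R_res.
    R values are NaN (with a warning left to the caller) where D_sig = 0.
    """
    rows = []
    noisy_levels = [lv for lv in table.levels if lv > table.levels[0]]
    for lv in noisy_levels:
        for tgt in table.targets:
            for k in table.samples_at(lv, tgt):
                try:
                    # the lower-level reference can be missing when a probe
                    # excluded a non-converged stimulus
                    d_lev = level_distance(table, lv, tgt, k)
                except KeyError:
                    d_lev = float("nan")
                d_res = residual_distance(table, lv, tgt, k)
                d_sig = signal_distance(table, lv, tgt, k)
                r_lev = d_lev / d_sig if d_sig and d_sig > 0 else float("nan")
                r_res = d_res / d_sig if d_sig and d_sig > 0 else float("nan")
                rows.append(
                    dict(level=lv, target=tgt, sample=k, D_lev=d_lev,
                         D_res=d_res, D_sig=d_sig, R_lev=r_lev, R_res=r_res)
                )
    return pd.DataFrame(rows)


def manifold_objective(table: FixedPointTable) -> float:
    """Variants-vs-concept compression objective.

    For each clean target i, the mean squared distance from i to its own
    variants, normalized by the mean squared distance from i to all stimuli
    of the other targets, summed over targets.  Identical within-target
    representations give 0; within = across gives the number of targets.
    """
    total = 0.0
    targets = table.targets
    if len(targets) < 2:
        raise ValueError("objective needs at least two targets")
    level0 = table.levels[0]
    for tgt in targets:
        anchor_key = (level0, tgt, table.samples_at(level0, tgt)[0])
        anchor = table[anchor_key]
        own = [table[key] for key in table.data
               if key[1] == tgt and key != anchor_key]
        if not own:
            raise ValueError(f"target {tgt} has no variants")
        other = [table[key] for key in table.data if key[1] != tgt]
        num = float(np.mean([np.sum((anchor - v) ** 2) for v in own]))
        den = float(np.mean([np.sum((anchor - v) ** 2) for v in other]))
        if den <= 0:
            raise ValueError("degenerate across-target distances")
        total += num / den
    return total


def compression_vs_familiarity_correlation(distance_series, familiarity_series):
    """Pearson correlation and least-squares line between two epoch series.

    Used to relate the epoch trajectory of mean relative distance to the
    trajectories of SI magnitude or lifetime-sparsity change.  Returns a dict
    with ``r``, ``slope``, ``intercept`` (NaN for fewer than 3 points or a
    constant series).
    """
    x = np.asarray(distance_series, dtype=float)
    y = np.asarray(familiarity_series, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    nan = dict(r=float("nan"), slope=float("nan"), intercept=float("nan"))
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return nan
    lr = stats.linregress(x, y)
    return dict(r=float(lr.rvalue), slope=float(lr.slope),
                intercept=float(lr.intercept))
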