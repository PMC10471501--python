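"""Regional heterogeneity: extreme-deviation thresholding, burden and overlap maps.

Positive and negative deviations are processed as fully separate pipelines.
Thresholding is strict (an extreme requires |z| strictly above the working
threshold).  Group overlap is reported as the proportion — not the raw count —
of group members with an extreme deviation in each region, to account for
group-size differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normative import DEFAULT_Z_THRESHOLD

SIGNS = ("positive", "negative")


def threshold_extremes(z, z_thr: float = DEFAULT_Z_THRESHOLD):
    """(pos, neg) boolean indicators: pos iff z > z_thr, neg iff z < −z_thr."""
    values = z.to_numpy() if isinstance(z, pd.DataFrame) else np.asarray(z, dtype=float)
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        if isinstance(z, pd.DataFrame):
            raise ValueError(f"non-finite z for subject {z.index[i]!r}, region {z.columns[j]}")
        raise ValueError(f"non-finite z at entry ({i}, {j})")
    pos, neg = values > z_thr, values < -z_thr
    if isinstance(z, pd.DataFrame):
        pos = pd.DataFrame(pos, index=z.index, columns=z.columns)
        neg = pd.DataFrame(neg, index=z.index, columns=z.columns)
    return pos, neg


def extremes_for_sign(z, sign: str, z_thr: float = DEFAULT_Z_THRESHOLD):
    pos, neg = threshold_extremes(z, z_thr)
    if sign not in SIGNS:
        raise ValueError(f"sign must be one of {SIGNS}")
    return pos if sign == "positive" else neg


def deviation_burden(pos, neg) -> pd.DataFrame:
    """Per-subject counts of extreme regions: (n_pos, n_neg, n_total)."""
    pos_arr = pos.to_numpy() if isinstance(pos, pd.DataFrame) else np.asarray(pos)
    neg_arr = neg.to_numpy() if isinstance(neg, pd.DataFrame) else np.asarray(neg)
    n_pos = pos_arr.sum(axis=1).astype(int)
    n_neg = neg_arr.sum(axis=1).astype(int)
    index = pos.index if isinstance(pos, pd.DataFrame) else pd.RangeIndex(len(n_pos))
    return pd.DataFrame({"n_pos": n_pos, "n_neg": n_neg, "n_total": n_pos + n_neg},
                        index=index)


@dataclass
class OverlapMap:
    """Per-region proportion of group members with an extreme (or circuit hit)."""

    group: str
    sign: str
    values: pd.Series  # indexed by region_id, in [0, 1]
    n_group: int

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# group={self.group} sign={self.sign} n={self.n_group}\n")
            self.values.rename("value").rename_axis("region_id").to_csv(fh, sep="\t")


def overlap_map(indicators, group: str = "", sign: str = "negative") -> OverlapMap:
    """Proportion of subjects (rows) flagged in each region (columns)."""
    arr = indicators.to_numpy() if isinstance(indicators, pd.DataFrame) else \
        np.asarray(indicators)
    if arr.shape[0] == 0:
        raise ValueError("overlap_map requires a nonempty group")
    values = arr.mean(axis=0).astype(float)
    cols = indicators.columns if isinstance(indicators, pd.DataFrame) else \
        pd.RangeIndex(arr.shape[1])
    return OverlapMap(group, sign, pd.Series(values, index=cols), arr.shape[0])


@dataclass
class DeltaOverlapMap:
    """Case minus control overlap, the unit of inference."""

    pair: tuple
    sign: str
    values: pd.Series  # in [-1, 1]


def delta_overlap(case: OverlapMap, control: OverlapMap) -> DeltaOverlapMap:
    if not case.values.index.equals(control.values.index):
        raise ValueError("overlap maps are on different region sets")
    if case.sign != control.sign:
        raise ValueError("overlap maps have different signs")
    return DeltaOverlapMap((case.group, control.group), case.sign,
                           case.values - control.values)


# --------------------------------------------------------------------------
# threshold-weighted overlap


def weighted_thresholds(z_min: float = 1.64, z_max: float = 3.10,
                        n_thr: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced thresholds (inclusive endpoints) and their linear weights
    W_th = 2 (th − z_min)/(z_max − z_min)."""
    if n_thr < 2:
        raise ValueError("n_thr must be >= 2")
    if not (z_max > z_min > 0):
        raise ValueError("need z_max > z_min > 0")
    th = np.exp(np.linspace(np.log(z_min), np.log(z_max), n_thr))
    w = 2.0 * (th - z_min) / (z_max - z_min)
    return th, w


def weighted_survival_scores(z, sign: str, z_min: float = 1.64, z_max: float = 3.10,
                             n_thr: int = 100):
    """Per-subject, per-region weighted threshold-survival score in [0, 1].

    The score is the weighted fraction of thresholds the subject's deviation
    survives (weight-then-integrate); the group map is its mean over subjects,
    so a region where every subject exceeds z_max at every threshold scores 1.
    """
    th, w = weighted_thresholds(z_min, z_max, n_thr)
    values = z.to_numpy() if isinstance(z, pd.DataFrame) else np.asarray(z, dtype=float)
    signed = values if sign == "positive" else -values
    # survives threshold k iff signed value strictly exceeds th_k
    scores = (signed[:, :, None] > th[None, None, :]) @ w / w.sum()
    if isinstance(z, pd.DataFrame):
        return pd.DataFrame(scores, index=z.index, columns=z.columns)
    return scores


@dataclass
class WeightedOverlapMap:
    group: str
    sign: str
    values: pd.Series
    z_min: float
    z_max: float
    n_thr: int
    n_group: int


def threshold_weighted_overlap(z, sign: str = "negative", group: str = "",
                               z_min: float = 1.64, z_max: float = 3.10,
                               n_thr: int = 100) -> WeightedOverlapMap:
    scores = weighted_survival_scores(z, sign, z_min, z_max, n_thr)
    arr = scores.to_numpy() if isinstance(scores, pd.DataFrame) else scores
    if arr.shape[0] == 0:
        raise ValueError("threshold_weighted_overlap requires a nonempty group")
    cols = z.columns if isinstance(z, pd.DataFrame) else pd.RangeIndex(arr.shape[1])
    return WeightedOverlapMap(group, sign, pd.Series(arr.mean(axis=0), index=cols),
                              z_min, z_max, n_thr, arr.shape[0])


def compare_burden(case_burdens, control_burdens, n_perm: int = 10_000,
                   seed: int = 0) -> float:
    """One-sided (cases > controls) permutation p for the difference in mean burden.

    Enumerates all group assignments exactly when feasible; otherwise Monte
    Carlo with the add-one estimator.  Delegated to the permutation machinery.
    """
    from .inference import permutation_mean_difference_p

    return permutation_mean_difference_p(np.asarray(case_burdens, dtype=float),
                                         np.asarray(control_burdens, dtype=float),
                                         n_perm=n_perm, seed=seed)
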