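"""Network-level aggregation of extreme deviations.

A network is deviant for a subject when at least one of its member regions
carries an extreme deviation; network overlap is the proportion of a group
with a deviant network.  Network size is deliberately not corrected for:
inference is case-versus-control within each network, never across networks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parcellation import NETWORKS_10, SUBCORTICAL_NETWORKS, ParcellationScheme
from .overlap import OverlapMap


def assign_networks(scheme: ParcellationScheme, level: int = 10) -> pd.Series:
    """Region -> network mapping at the 10- or 20-network level."""
    if level not in (10, 20):
        raise ValueError("level must be 10 or 20")
    col = "network10" if level == 10 else "network20"
    labels = scheme.regions[col]
    if labels.isna().any():
        bad = labels.index[labels.isna()][0]
        raise ValueError(f"region {bad} has no {col} label")
    subcortical = scheme.regions["compartment"] == "subcortex"
    bad = labels[subcortical & ~labels.isin(SUBCORTICAL_NETWORKS)]
    if len(bad):
        raise ValueError(
            f"subcortical region {bad.index[0]} carries a cortical network label "
            f"{bad.iloc[0]!r}")
    return labels.copy()


def membership_matrix(mapping: pd.Series) -> tuple[np.ndarray, list]:
    """Boolean regions x networks matrix plus the network name order."""
    names = sorted(mapping.unique(), key=lambda x: (x not in NETWORKS_10, str(x)))
    M = np.stack([(mapping == name).to_numpy() for name in names], axis=1)
    return M, names


def network_deviance(extremes, mapping: pd.Series) -> pd.DataFrame:
    """Per-subject, per-network OR of member-region extreme indicators."""
    if isinstance(extremes, pd.DataFrame):
        arr = extremes.loc[:, mapping.index].to_numpy()
        index = extremes.index
    else:
        arr = np.atleast_2d(np.asarray(extremes))
        index = pd.RangeIndex(arr.shape[0])
    M, names = membership_matrix(mapping)
    D = arr.astype(np.float32) @ M.astype(np.float32) > 0.5
    return pd.DataFrame(D, index=index, columns=names)


def network_overlap(deviance: pd.DataFrame, group: str = "",
                    sign: str = "negative") -> OverlapMap:
    """Proportion of the group with at least one extreme in each network."""
    if deviance.shape[0] == 0:
        raise ValueError("network_overlap requires a nonempty group")
    return OverlapMap(group, sign,
                      pd.Series(deviance.to_numpy().mean(axis=0),
                                index=deviance.columns),
                      deviance.shape[0])
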