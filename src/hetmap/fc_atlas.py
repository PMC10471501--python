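"""Synthetic normative functional-connectivity atlas.

Stands in for a resting-state cohort of healthy individuals: each subject
contributes a grayordinate x time matrix in which grayordinates of the same
functional network share a latent signal (weight ``community_strength``), an
optional hub latent is broadcast to the hub regions' coupled set, and the rest
is white noise.  The grayordinate adjacency is a symmetrised k-nearest-neighbour
graph built within each compartment, with cortex and subcortex kept as two
disconnected components (cluster-based statistics are computed separately for
the two compartments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .parcellation import NETWORKS_10, ParcellationScheme


@dataclass
class FCAtlas:
    """Normative cohort of grayordinate time series plus geometry."""

    timeseries: np.ndarray          # (n_subjects, n_gray, T)
    adjacency: sp.csr_matrix        # symmetric, no self-loops, 2 components
    lookup: np.ndarray              # grayordinate -> region_id
    cortex_gray: np.ndarray         # boolean mask over grayordinates
    meta: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return self.timeseries.shape[0]

    @property
    def n_gray(self) -> int:
        return self.timeseries.shape[1]

    def validate(self) -> None:
        a = self.adjacency
        if (a != a.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency must have no self-loops")
        n_comp, labels = connected_components(a, directed=False)
        if n_comp != 2:
            raise ValueError(f"adjacency must have exactly 2 components, found {n_comp}")
        if len(np.unique(labels[self.cortex_gray])) != 1:
            raise ValueError("cortex grayordinates split across components")

    # ------------------------------------------------------------------ I/O
    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for s in range(self.n_subjects):
            np.savetxt(directory / f"subject_{s:03d}.tsv",
                       self.timeseries[s], delimiter="\t", fmt="%.6f")
        coo = sp.triu(self.adjacency).tocoo()
        pd.DataFrame({"i": coo.row, "j": coo.col}).to_csv(
            directory / "adjacency_edges.tsv", sep="\t", index=False)
        pd.DataFrame({"grayordinate": np.arange(self.n_gray),
                      "region_id": self.lookup,
                      "cortex": self.cortex_gray.astype(int)}).to_csv(
            directory / "lookup.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, directory: str | Path) -> "FCAtlas":
        directory = Path(directory)
        files = sorted(directory.glob("subject_*.tsv"))
        if not files:
            raise FileNotFoundError(f"no subject_*.tsv files in {directory}")
        ts = np.stack([np.loadtxt(f, delimiter="\t") for f in files])
        lk = pd.read_csv(directory / "lookup.tsv", sep="\t")
        edges = pd.read_csv(directory / "adjacency_edges.tsv", sep="\t")
        n = len(lk)
        a = sp.coo_matrix((np.ones(len(edges)), (edges["i"], edges["j"])), shape=(n, n))
        a = ((a + a.T) > 0).astype(np.int8).tocsr()
        atlas = cls(ts, a, lk["region_id"].to_numpy(),
                    lk["cortex"].to_numpy().astype(bool))
        atlas.validate()
        return atlas


def _knn_graph(coords: np.ndarray, k: int) -> sp.csr_matrix:
    """Symmetrised k-NN graph, forced connected by bridging nearest components."""
    n = len(coords)
    k = min(k, n - 1)
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    a = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    a = ((a + a.T) > 0).astype(np.int8).tolil()
    a.setdiag(0)
    while True:
        n_comp, labels = connected_components(a.tocsr(), directed=False)
        if n_comp == 1:
            break
        c0 = np.flatnonzero(labels == 0)
        c1 = np.flatnonzero(labels != 0)
        d = np.linalg.norm(coords[c0][:, None, :] - coords[c1][None, :, :], axis=2)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        a[c0[i], c1[j]] = 1
        a[c1[j], c0[i]] = 1
    return a.tocsr()


def hub_broadcast_set(scheme: ParcellationScheme, hub_regions) -> np.ndarray:
    """Regions receiving the hub latent: the hubs plus every region sharing a
    10-network label with a hub (boolean over scheme order)."""
    hub_regions = list(hub_regions)
    nets = set(scheme.regions.loc[hub_regions, "network10"])
    mask = scheme.regions["network10"].isin(nets).to_numpy()
    mask[scheme.regions.index.get_indexer(hub_regions)] = True
    return mask


def reference_coupling(
    scheme: ParcellationScheme,
    community_strength: float = 0.6,
    hub_regions=(),
    hub_strength: float = 0.5,
    noise: float = 1.0,
    gray_per_region: int | None = None,
) -> np.ndarray:
    """Model-implied region x region correlation matrix of the synthetic atlas.

    Region signals average ``g`` grayordinates, so idiosyncratic noise variance
    is ``noise**2 / g`` while latent contributions are shared within a region.
    """
    if gray_per_region is None:
        gray_per_region = int(scheme.meta.get("gray_per_region", 1))
    net = scheme.regions["network10"].to_numpy()
    same_net = (net[:, None] == net[None, :])
    cs2, hs2 = community_strength**2, hub_strength**2
    in_b = hub_broadcast_set(scheme, hub_regions) if len(list(hub_regions)) else \
        np.zeros(scheme.n_regions, dtype=bool)
    cov = cs2 * same_net + hs2 * np.outer(in_b, in_b)
    var = cs2 + hs2 * in_b + noise**2 / gray_per_region
    np.fill_diagonal(cov, var)
    d = 1.0 / np.sqrt(var)
    return cov * np.outer(d, d)


def make_fc_atlas(
    scheme: ParcellationScheme,
    n_subjects: int,
    T: int,
    community_strength: float = 0.6,
    hub_regions=(),
    hub_strength: float = 0.5,
    noise: float = 1.0,
    knn: int = 5,
    seed: int = 0,
) -> FCAtlas:
    """Simulate the normative FC cohort; deterministic given ``seed``."""
    if n_subjects < 10:
        raise ValueError("n_subjects must be >= 10")
    if T < 3:
        raise ValueError("T must be >= 3")
    if T < 50:
        warnings.warn(f"T={T} is small; correlation estimates will be unstable")

    rng = np.random.default_rng(seed)
    region_net = scheme.regions["network10"].to_numpy()
    net_index = {n: i for i, n in enumerate(NETWORKS_10)}
    gray_net = np.array([net_index[region_net[i]]
                         for i in scheme.regions.index.get_indexer(scheme.gray_region)])
    in_b_region = hub_broadcast_set(scheme, hub_regions) if len(list(hub_regions)) else \
        np.zeros(scheme.n_regions, dtype=bool)
    gray_in_b = in_b_region[scheme.regions.index.get_indexer(scheme.gray_region)]

    G = scheme.n_gray
    ts = np.empty((n_subjects, G, T), dtype=np.float32)
    for s in range(n_subjects):
        latents = rng.standard_normal((len(NETWORKS_10), T))
        hub = rng.standard_normal(T)
        x = community_strength * latents[gray_net]
        x += hub_strength * gray_in_b[:, None] * hub[None, :]
        x += noise * rng.standard_normal((G, T))
        ts[s] = x

    cortex_gray = scheme.gray_compartment_mask("cortex")
    blocks = []
    order = []
    for mask in (cortex_gray, ~cortex_gray):
        idx = np.flatnonzero(mask)
        order.append(idx)
        blocks.append(_knn_graph(scheme.gray_coords[idx], knn))
    # reassemble into global indexing
    a = sp.lil_matrix((G, G), dtype=np.int8)
    for idx, block in zip(order, blocks):
        coo = block.tocoo()
        a[idx[coo.row], idx[coo.col]] = 1
    atlas = FCAtlas(
        ts, a.tocsr(), scheme.gray_region.copy(), cortex_gray,
        meta=dict(n_subjects=n_subjects, T=T, community_strength=community_strength,
                  hub_regions=list(hub_regions), hub_strength=hub_strength,
                  noise=noise, knn=knn, seed=seed),
    )
    atlas.validate()
    return atlas
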