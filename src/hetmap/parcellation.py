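"""Synthetic brain parcellation: regions on per-hemisphere spheres with network labels.

The parcellation is a miniature analogue of a surface-based cortical atlas plus a
subcortical segmentation.  Each cortical hemisphere is its own unit sphere (as in
surface-based spin testing, which only requires spherical coordinates); homotopic
regions in the two hemispheres share index order via a mirror through the x axis.
Cortical regions carry two nested network labellings: a coarse 7-network scheme
(10 networks once the three subcortical groups are added) and a 17-network
refinement (20 with subcortex).  Every region owns a disjoint set of grayordinates
jittered around the region centroid; grayordinates are the sampling units of the
functional-connectivity atlas.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CORTICAL_NETWORKS_7 = ["VIS", "SM", "DA", "SAL/VA", "L", "F", "DM"]
SUBCORTICAL_NETWORKS = ["MeTe", "Tha", "Bas"]
NETWORKS_10 = CORTICAL_NETWORKS_7 + SUBCORTICAL_NETWORKS

#: 17-network refinement of the 7 cortical networks (nested by construction).
NETWORK_17_CHILDREN = {
    "VIS": ["VisCent", "VisPeri"],
    "SM": ["SomMotA", "SomMotB"],
    "DA": ["DorsAttnA", "DorsAttnB"],
    "SAL/VA": ["SalVentAttnA", "SalVentAttnB"],
    "L": ["LimbicA", "LimbicB"],
    "F": ["ContA", "ContB", "ContC"],
    "DM": ["DefaultA", "DefaultB", "DefaultC", "TempPar"],
}

_MIRROR = np.diag([-1.0, 1.0, 1.0])


@dataclass
class ParcellationScheme:
    """Region catalogue plus grayordinate geometry.

    Attributes
    ----------
    regions : pandas.DataFrame
        One row per region, indexed by integer ``region_id``; columns
        ``hemisphere`` ({L, R, NA}), ``compartment`` ({cortex, subcortex}),
        ``x, y, z`` (unit-sphere coordinates for cortex; embedded cluster
        coordinates for subcortex), ``network10`` and ``network20``.
    gray_coords : numpy.ndarray, shape (G, 3)
        Embedding coordinates of every grayordinate (used for the k-NN graph).
    gray_region : numpy.ndarray, shape (G,)
        ``region_id`` owning each grayordinate.
    """

    regions: pd.DataFrame
    gray_coords: np.ndarray
    gray_region: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def region_ids(self) -> np.ndarray:
        return self.regions.index.to_numpy()

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_gray(self) -> int:
        return len(self.gray_region)

    def is_cortex(self) -> np.ndarray:
        return (self.regions["compartment"] == "cortex").to_numpy()

    def cortical_coords(self, hemisphere: str) -> tuple[np.ndarray, np.ndarray]:
        """(region_ids, coords) of one cortical hemisphere, in scheme order."""
        m = (self.regions["compartment"] == "cortex") & (self.regions["hemisphere"] == hemisphere)
        sub = self.regions.loc[m, ["x", "y", "z"]]
        return sub.index.to_numpy(), sub.to_numpy()

    def grayordinates(self, region_id: int) -> np.ndarray:
        return np.flatnonzero(self.gray_region == region_id)

    def gray_compartment_mask(self, compartment: str) -> np.ndarray:
        comp = self.regions["compartment"].reindex(self.gray_region).to_numpy()
        return comp == compartment

    def subset(self, region_ids) -> "ParcellationScheme":
        """Restrict the scheme to ``region_ids`` (scheme order preserved).

        Supports cohorts with declared-missing regions; grayordinates of
        dropped regions are removed."""
        keep_ids = [rid for rid in self.region_ids if rid in set(region_ids)]
        keep_gray = np.isin(self.gray_region, keep_ids)
        return ParcellationScheme(self.regions.loc[keep_ids].copy(),
                                  self.gray_coords[keep_gray],
                                  self.gray_region[keep_gray], dict(self.meta))

    def validate(self) -> None:
        reg = self.regions
        if reg.index.duplicated().any():
            raise ValueError("duplicate region_id in parcellation")
        cortex = reg[reg["compartment"] == "cortex"]
        norms = np.linalg.norm(cortex[["x", "y", "z"]].to_numpy(), axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("cortical coordinates must lie on the unit sphere")
        bad = reg.loc[(reg["compartment"] == "subcortex")
                      & ~reg["network10"].isin(SUBCORTICAL_NETWORKS)]
        if len(bad):
            raise ValueError(f"subcortical regions with cortical network labels: {list(bad.index)}")
        counts = pd.Series(self.gray_region).value_counts()
        missing = set(reg.index) - set(counts.index)
        if missing:
            raise ValueError(f"regions without grayordinates: {sorted(missing)}")

    # ------------------------------------------------------------------ I/O
    def write(self, tsv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        tsv_path = Path(tsv_path)
        out = self.regions.reset_index().rename(columns={"index": "region_id"})
        out.to_csv(tsv_path, sep="\t", index=False)
        if sidecar_path is None:
            sidecar_path = tsv_path.with_suffix(".json")
        sidecar = {
            "grayordinates": {
                str(rid): [int(g) for g in self.grayordinates(rid)] for rid in self.region_ids
            },
            "gray_coords": [[round(float(v), 8) for v in row] for row in self.gray_coords],
            "meta": self.meta,
        }
        Path(sidecar_path).write_text(json.dumps(sidecar))

    @classmethod
    def read(cls, tsv_path: str | Path, sidecar_path: str | Path | None = None) -> "ParcellationScheme":
        tsv_path = Path(tsv_path)
        # keep_default_na: the literal hemisphere label "NA" must survive
        reg = pd.read_csv(tsv_path, sep="\t", keep_default_na=False,
                          na_values=[""]).set_index("region_id")
        if sidecar_path is None:
            sidecar_path = tsv_path.with_suffix(".json")
        sidecar = json.loads(Path(sidecar_path).read_text())
        coords = np.asarray(sidecar["gray_coords"], dtype=float)
        gray_region = np.empty(len(coords), dtype=int)
        seen = np.zeros(len(coords), dtype=bool)
        for rid, grays in sidecar["grayordinates"].items():
            grays = np.asarray(grays, dtype=int)
            if seen[grays].any():
                raise ValueError(f"grayordinate sets are not disjoint (region {rid})")
            seen[grays] = True
            gray_region[grays] = int(rid)
        if not seen.all():
            raise ValueError("grayordinates not covered by any region")
        scheme = cls(reg, coords, gray_region, meta=sidecar.get("meta", {}))
        scheme.validate()
        return scheme


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _patch_labels(coords: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-centre (geodesic Voronoi) labels; every centre keeps >=1 member."""
    lab = np.argmax(coords @ centers.T, axis=1)
    for k in range(len(centers)):
        if not np.any(lab == k):
            # steal the region closest to the empty centre so no label vanishes
            cand = np.argsort(-(coords @ centers[k]))
            for c in cand:
                if np.sum(lab == lab[c]) > 1:
                    lab[c] = k
                    break
    return lab


def make_parcellation(
    n_cortex: int, n_subcortex: int, gray_per_region: int, seed: int
) -> ParcellationScheme:
    """Generate a deterministic synthetic parcellation.

    Parameters
    ----------
    n_cortex : int
        Number of cortical regions; must be even (split equally across L/R).
    n_subcortex : int
        Number of subcortical regions (>=3 so that all three subcortical
        groups — medial temporal, thalamus, basal ganglia — are represented).
    gray_per_region : int
        Grayordinates per region (identical for every region).
    seed : int
        RNG seed; the scheme is a pure function of its arguments.
    """
    if n_cortex <= 0 or n_subcortex <= 0 or gray_per_region <= 0:
        raise ValueError("n_cortex, n_subcortex and gray_per_region must be positive")
    if n_cortex % 2:
        raise ValueError("n_cortex must be even (regions are split across hemispheres)")
    if n_subcortex < 3:
        raise ValueError("n_subcortex must be >=3 to cover MeTe/Tha/Bas")

    rng = np.random.default_rng(seed)
    n_hemi = n_cortex // 2
    left = _fibonacci_sphere(n_hemi)
    # random global rotation so patches differ across seeds
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    left = left @ q.T
    right = left @ _MIRROR.T  # homotopic mirror

    # contiguous 7-network patches, identical in both hemispheres (left frame)
    centers7 = rng.standard_normal((7, 3))
    centers7 /= np.linalg.norm(centers7, axis=1, keepdims=True)
    net7 = _patch_labels(left, centers7)

    # nested 17-network refinement: sub-patches inside each 7-network patch
    net17 = np.empty(n_hemi, dtype=object)
    for k, parent in enumerate(CORTICAL_NETWORKS_7):
        members = np.flatnonzero(net7 == k)
        children = NETWORK_17_CHILDREN[parent]
        m = min(len(children), len(members))
        sub_centers = left[rng.choice(members, size=m, replace=False)]
        sub = _patch_labels(left[members], sub_centers)
        for j, region in zip(sub, members):
            net17[region] = children[j % len(children)]

    rows = []
    region_id = 1
    for hemi, coords in (("L", left), ("R", right)):
        for i in range(n_hemi):
            rows.append(
                dict(
                    region_id=region_id,
                    hemisphere=hemi,
                    compartment="cortex",
                    x=coords[i, 0], y=coords[i, 1], z=coords[i, 2],
                    network10=CORTICAL_NETWORKS_7[net7[i]],
                    network20=net17[i],
                )
            )
            region_id += 1

    # subcortex: three contiguous anatomical groups in a separate embedded cluster
    sub_groups = np.array_split(np.arange(n_subcortex), 3)
    sub_centers = rng.standard_normal((n_subcortex, 3)) * 0.25 + np.array([0.0, 0.0, -3.0])
    for g, ids in enumerate(sub_groups):
        for i in ids:
            rows.append(
                dict(
                    region_id=region_id,
                    hemisphere="NA",
                    compartment="subcortex",
                    x=sub_centers[i, 0], y=sub_centers[i, 1], z=sub_centers[i, 2],
                    network10=SUBCORTICAL_NETWORKS[g],
                    network20=SUBCORTICAL_NETWORKS[g],
                )
            )
            region_id += 1

    reg = pd.DataFrame(rows).set_index("region_id")

    # grayordinates: jitter around centroids; hemispheres embedded apart so the
    # k-NN graph never bridges them by accident (an explicit bridge is added by
    # the atlas builder to keep cortex a single component)
    jitter_scale = 0.35 * np.sqrt(4.0 * np.pi / n_hemi)
    coords_list = []
    gray_region = []
    for rid, row in reg.iterrows():
        c = np.array([row["x"], row["y"], row["z"]])
        if row["compartment"] == "cortex":
            pts = c + rng.standard_normal((gray_per_region, 3)) * jitter_scale
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            shift = np.array([-2.5, 0.0, 0.0]) if row["hemisphere"] == "L" else np.array([2.5, 0.0, 0.0])
            pts = pts + shift
        else:
            pts = c + rng.standard_normal((gray_per_region, 3)) * 0.08
        coords_list.append(pts)
        gray_region.extend([rid] * gray_per_region)

    scheme = ParcellationScheme(
        regions=reg,
        gray_coords=np.vstack(coords_list),
        gray_region=np.asarray(gray_region, dtype=int),
        meta=dict(n_cortex=n_cortex, n_subcortex=n_subcortex,
                  gray_per_region=gray_per_region, seed=seed),
    )
    scheme.validate()
    return scheme
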