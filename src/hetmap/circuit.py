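"""Circuit mapping: normative functional circuitry of deviant seed regions.

Mirrors lesion-network-mapping logic: each region that expresses an extreme
deviation in anyone is used as a seed in the normative FC cohort; per atlas
subject the seed's mean time course is correlated with every grayordinate and
Fisher r-to-z transformed; the subject maps are aggregated with a one-sample
t-test, TFCE-enhanced, and thresholded by sign-flipping max-statistic
permutation FWE (run separately for cortex and subcortex); surviving
grayordinates are parcellated back to regions (a region joins the circuit when
more than ``frac`` of its grayordinates survive).  A subject's union map is the
elementwise OR of the circuits of all their extreme seeds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .fc_atlas import FCAtlas
from .inference import gpd_tail_pvalues
from .parcellation import ParcellationScheme
from .tfce import tfce_enhance_batch

T_CAP = 50.0  # |t| cap before TFCE; see docs/methods.md (seed self-correlation)


def seed_fc_map(timeseries: np.ndarray, seed_grays: np.ndarray) -> np.ndarray:
    """Fisher-z seed FC map for one atlas subject.

    The seed time course is the mean over the seed's grayordinates; Pearson r
    against every grayordinate (the seed's own included) is atanh-transformed,
    with |r| clamped to 1 - 1e-12 first so identical series give a large
    finite value rather than infinity.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    if len(seed_grays) == 0:
        raise ValueError("seed has no grayordinates")
    seed_tc = ts[seed_grays].mean(axis=0)
    if np.std(seed_tc) == 0:
        raise ValueError("zero-variance seed time course")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance grayordinate time course")
    zs = (ts - ts.mean(axis=1, keepdims=True)) / sd[:, None]
    zseed = (seed_tc - seed_tc.mean()) / seed_tc.std()
    r = zs @ zseed / ts.shape[1]
    clamped = np.abs(r) >= 1.0 - 1e-12
    clamped[seed_grays] = False  # the seed's own grayordinates trivially hit r=1
    if clamped.any():
        warnings.warn("correlations at |r|=1 clamped before Fisher transform")
    return np.arctanh(np.clip(r, -(1 - 1e-12), 1 - 1e-12))


def group_t_map(fisher_maps: np.ndarray) -> np.ndarray:
    """One-sample t (against 0) across atlas subjects at each grayordinate.

    Zero across-subject variance yields a signed infinite sentinel (with a
    warning) unless the mean is also zero, in which case t = 0.
    """
    Z = np.asarray(fisher_maps, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("group_t_map requires >= 2 atlas subjects")
    n = Z.shape[0]
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    zero = sd == 0
    if np.any(zero & (mean != 0)):
        warnings.warn("zero across-subject variance; t set to signed infinity")
    with np.errstate(divide="ignore", invalid="ignore"):
        t[~zero] = mean[~zero] / (sd[~zero] / np.sqrt(n))
    t[zero & (mean > 0)] = np.inf
    t[zero & (mean < 0)] = -np.inf
    return t


def _capped_t(Z: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t = group_t_map(Z)
    return np.clip(np.nan_to_num(t, posinf=T_CAP, neginf=-T_CAP), -T_CAP, T_CAP)


def fwe_binarize(fisher_maps: np.ndarray, adjacency, n_perm: int = 500,
                 alpha: float = 0.025, seed: int = 0, E: float = 0.5,
                 H: float = 2.0) -> dict:
    """Binary significance map for one compartment by TFCE + max-statistic FWE.

    The null is built by sign-flipping subjects' Fisher-z maps (exchangeable
    under the symmetric null of no coupling); per-grayordinate FWE p-values
    come from counting against the null maxima with a generalized-Pareto tail
    refinement; significance is ``p < alpha``.
    """
    Z = np.asarray(fisher_maps, dtype=float)
    if Z.shape[0] < 2:
        raise ValueError("fwe_binarize requires >= 2 atlas subjects")
    if n_perm < 50:
        warnings.warn(f"n_perm={n_perm} gives an unstable GPD tail fit")
    n = Z.shape[0]
    rng = np.random.default_rng(seed)
    t_obs = _capped_t(Z)

    signs = rng.choice(np.array([-1.0, 1.0]), size=(n_perm, n))
    M1 = signs @ Z / n
    msq = (Z ** 2).mean(axis=0)
    var = np.maximum((msq - M1 ** 2) * n / (n - 1), 1e-30)
    t_null = np.clip(M1 / np.sqrt(var / n), -T_CAP, T_CAP)

    batch = np.vstack([t_obs[None, :], t_null])
    enhanced = tfce_enhance_batch(batch, adjacency, E=E, H=H, dh=None)
    tfce_obs = enhanced[0]
    null_max = enhanced[1:].max(axis=1)
    p = gpd_tail_pvalues(null_max, tfce_obs, seed=seed)
    return dict(significant=p < alpha, p_fwe=p, tfce=tfce_obs,
                null_max=null_max)


def parcellate_binary(binary_gray: np.ndarray, lookup: np.ndarray,
                      region_ids: np.ndarray, frac: float = 0.5) -> np.ndarray:
    """Region is in the circuit iff the surviving fraction of its
    grayordinates strictly exceeds ``frac``."""
    binary_gray = np.asarray(binary_gray, dtype=bool)
    out = np.zeros(len(region_ids), dtype=np.int8)
    for i, rid in enumerate(region_ids):
        grays = np.flatnonzero(lookup == rid)
        if len(grays) == 0:
            raise ValueError(f"region {rid} has zero grayordinates")
        out[i] = binary_gray[grays].mean() > frac
    return out


@dataclass
class SeedCircuit:
    """Binary regional map of areas significantly coupled to one seed."""

    seed_region: int
    regions: np.ndarray  # int8 over scheme region order
    provenance: dict = field(default_factory=dict)


@dataclass
class CircuitCache:
    """Seed-region -> circuit lookup, persisted as a regions x regions table."""

    matrix: pd.DataFrame  # rows: seed region_id, cols: region_id, int8
    provenance: dict = field(default_factory=dict)

    def circuit(self, region_id: int) -> np.ndarray:
        if region_id not in self.matrix.index:
            raise KeyError(f"no cached circuit for seed region {region_id}")
        return self.matrix.loc[region_id].to_numpy()

    def as_array(self, region_ids: np.ndarray) -> np.ndarray:
        """Full [R x R] matrix in ``region_ids`` order (rows = seeds)."""
        missing = set(region_ids) - set(self.matrix.index)
        if missing:
            raise KeyError(f"circuits missing for seed regions {sorted(missing)}")
        return self.matrix.loc[region_ids, region_ids].to_numpy()

    def write(self, tsv_path: str | Path, provenance_path: str | Path | None = None) -> None:
        tsv_path = Path(tsv_path)
        self.matrix.rename_axis("seed_region").to_csv(tsv_path, sep="\t")
        if provenance_path is None:
            provenance_path = tsv_path.with_suffix(".json")
        Path(provenance_path).write_text(json.dumps(self.provenance))

    @classmethod
    def read(cls, tsv_path: str | Path, provenance_path: str | Path | None = None) -> "CircuitCache":
        tsv_path = Path(tsv_path)
        m = pd.read_csv(tsv_path, sep="\t").set_index("seed_region")
        m.columns = m.columns.astype(int)
        if provenance_path is None:
            provenance_path = tsv_path.with_suffix(".json")
        prov = json.loads(Path(provenance_path).read_text()) if Path(provenance_path).exists() else {}
        return cls(m.astype(np.int8), prov)


def compute_circuit(atlas: FCAtlas, scheme: ParcellationScheme, seed_region: int,
                    n_perm: int = 500, alpha: float = 0.025, frac: float = 0.5,
                    seed: int = 0) -> SeedCircuit:
    """Map one seed's circuit (both compartments tested independently)."""
    grays = atlas.lookup
    seed_grays = np.flatnonzero(grays == seed_region)
    F = np.stack([seed_fc_map(atlas.timeseries[s], seed_grays)
                  for s in range(atlas.n_subjects)])
    sig = np.zeros(atlas.n_gray, dtype=bool)
    for comp_i, mask in enumerate((atlas.cortex_gray, ~atlas.cortex_gray)):
        cols = np.flatnonzero(mask)
        sub_adj = atlas.adjacency[cols][:, cols]
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(int(seed_region), comp_i))
        res = fwe_binarize(F[:, cols], sub_adj, n_perm=n_perm, alpha=alpha,
                           seed=int(ss.generate_state(1)[0] % (2**31)))
        sig[cols] = res["significant"]
    vec = parcellate_binary(sig, grays, scheme.region_ids, frac=frac)
    return SeedCircuit(seed_region, vec,
                       provenance=dict(n_perm=n_perm, alpha_fwe=alpha,
                                       parcel_frac=frac, seed=seed))


def compute_circuit_cache(atlas: FCAtlas, scheme: ParcellationScheme,
                          seed_regions=None, n_perm: int = 500,
                          alpha: float = 0.025, frac: float = 0.5,
                          seed: int = 0) -> CircuitCache:
    """Circuits for every requested seed (default: all regions), computed once
    per unique seed; deterministic given the atlas and the RNG seed."""
    if seed_regions is None:
        seed_regions = scheme.region_ids
    rows = {}
    for rid in seed_regions:
        rows[int(rid)] = compute_circuit(atlas, scheme, int(rid), n_perm=n_perm,
                                         alpha=alpha, frac=frac, seed=seed).regions
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix.columns = scheme.region_ids
    matrix.index.name = "seed_region"
    return CircuitCache(matrix.astype(np.int8),
                        provenance=dict(n_perm=n_perm, alpha_fwe=alpha,
                                        parcel_frac=frac, seed=seed,
                                        atlas=dict(atlas.meta)))


def union_map(extreme_regions, cache: CircuitCache, n_regions: int | None = None) -> np.ndarray:
    """Elementwise OR over the subject's seed circuits; empty seed set gives an
    all-zero map."""
    extreme_regions = list(extreme_regions)
    if not extreme_regions:
        return np.zeros(cache.matrix.shape[1] if n_regions is None else n_regions,
                        dtype=np.int8)
    acc = None
    for rid in extreme_regions:
        circ = cache.circuit(rid)
        acc = circ.copy() if acc is None else np.maximum(acc, circ)
    return acc


def union_maps_for_group(extremes: pd.DataFrame, cache: CircuitCache) -> pd.DataFrame:
    """Union maps for all subjects at once (rows subjects, columns regions)."""
    region_ids = np.asarray(extremes.columns, dtype=int)
    C = cache.as_array(region_ids).astype(np.float32)
    U = (extremes.to_numpy().astype(np.float32) @ C > 0.5).astype(np.int8)
    return pd.DataFrame(U, index=extremes.index, columns=extremes.columns)


def circuit_overlap(union: pd.DataFrame, group: str = "", sign: str = "negative"):
    """Proportion of the group with deviant-coupled FC at each region."""
    from .overlap import overlap_map

    return overlap_map(union, group=group, sign=sign)
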