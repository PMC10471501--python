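"""Permutation inference for overlap differences: two null models, GPD tails, FDR.

Two complementary null models are provided.  The *group-label* permutation
shuffles case/control labels and is sensitive to any overlap difference,
including those driven purely by a higher deviation burden in one group.  The
*spatial* permutation rotates each subject's cortical deviation map on the
sphere (a value-preserving bijection obtained by Hungarian assignment between
rotated and original region positions) and shuffles subcortical values, then
re-runs the downstream aggregation; because each surrogate preserves every
subject's deviation burden exactly, it isolates *preferential targeting* of
specific regions/circuits/networks from burden differences.

Small permutation p-values are refined with a generalized Pareto (GPD)
approximation of the null tail: exceedances over an adaptively lowered
threshold are fitted by probability-weighted moments and accepted by an
Anderson–Darling goodness-of-fit test with a parametric-bootstrap null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .overlap import extremes_for_sign, weighted_survival_scores

_MIRROR = np.diag([-1.0, 1.0, 1.0])


# --------------------------------------------------------------------------
# FDR


def fdr_correct(p, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at level ``q``."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


# --------------------------------------------------------------------------
# generalized Pareto tail approximation


def _gpd_fit_pwm(x: np.ndarray) -> tuple[float, float]:
    """Probability-weighted-moment GPD fit (Hosking & Wallis); returns
    (shape c in scipy convention, scale)."""
    xs = np.sort(x)
    n = len(xs)
    b0 = xs.mean()
    b1 = (xs * (n - 1 - np.arange(n)) / (n - 1)).mean()  # E[X (1 - F(X))]
    denom = b0 - 2.0 * b1
    if denom <= 0:
        return 0.5, max(b0, 1e-300)  # very heavy tail; clamp shape
    k = b0 / denom - 2.0
    scale = 2.0 * b0 * b1 / denom
    return float(-k), float(max(scale, 1e-300))


def _anderson_darling(x: np.ndarray, c: float, scale: float) -> float:
    u = np.sort(stats.genpareto.cdf(np.sort(x), c, scale=scale))
    u = np.clip(u, 1e-12, 1 - 1e-12)
    n = len(u)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log(1 - u[::-1]))))


def _gpd_accepted_fit(exceed: np.ndarray, n_bootstrap: int, gof_alpha: float,
                      rng: np.random.Generator) -> tuple[float, float] | None:
    c, scale = _gpd_fit_pwm(exceed)
    a2 = _anderson_darling(exceed, c, scale)
    worse = 0
    for _ in range(n_bootstrap):
        sim = stats.genpareto.rvs(c, scale=scale, size=len(exceed), random_state=rng)
        cb, sb = _gpd_fit_pwm(sim)
        if _anderson_darling(sim, cb, sb) >= a2:
            worse += 1
    p_gof = (1 + worse) / (n_bootstrap + 1)
    return (c, scale) if p_gof > gof_alpha else None


def _gpd_tail(null_sorted_desc: np.ndarray, tail_frac: float, n_bootstrap: int,
              gof_alpha: float, seed: int):
    """Find an accepted GPD tail fit; returns (threshold, tail_mass, c, scale)
    or None.  The number of exceedances is lowered in steps of 10 order
    statistics until the goodness-of-fit test accepts."""
    n = len(null_sorted_desc)
    rng = np.random.default_rng(seed)
    n_exc = int(tail_frac * n)
    while n_exc >= 10:
        thr = 0.5 * (null_sorted_desc[n_exc - 1] + null_sorted_desc[n_exc])
        exceed = null_sorted_desc[:n_exc] - thr
        if exceed.max() <= 0 or np.ptp(exceed) == 0:
            return None  # degenerate (massively tied) tail
        fit = _gpd_accepted_fit(exceed, n_bootstrap, gof_alpha, rng)
        if fit is not None:
            return thr, n_exc / n, fit[0], fit[1]
        n_exc -= 10
    return None


def gpd_tail_pvalue(null, observed: float, tail_frac: float = 0.10,
                    n_bootstrap: int = 60, gof_alpha: float = 0.05,
                    seed: int = 0) -> float:
    """Upper-tail p-value of ``observed`` against a permutation null sample.

    Below the tail threshold (or when the sample is too small for tail
    modelling) the add-one empirical proportion is returned; above it, the
    GPD tail estimate ``tail_mass * SF_GPD(observed - threshold)``.
    """
    return float(gpd_tail_pvalues(null, np.asarray([observed]), tail_frac,
                                  n_bootstrap, gof_alpha, seed)[0])


def gpd_tail_pvalues(null, observed, tail_frac: float = 0.10,
                     n_bootstrap: int = 60, gof_alpha: float = 0.05,
                     seed: int = 0) -> np.ndarray:
    null = np.asarray(null, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n = len(null)
    emp = (1.0 + (null[None, :] >= observed[:, None]).sum(axis=1)) / (n + 1.0)
    if n < 100:
        return emp
    xs = np.sort(null)[::-1]
    fit = _gpd_tail(xs, tail_frac, n_bootstrap, gof_alpha, seed)
    if fit is None:
        warnings.warn("GPD goodness-of-fit never accepted; using empirical tail")
        return np.maximum(emp, 1.0 / (n + 1.0))
    thr, tail_mass, c, scale = fit
    out = emp.copy()
    hi = observed > thr
    if hi.any():
        sf = stats.genpareto.sf(observed[hi] - thr, c, scale=scale)
        # floor: GPD extrapolation beyond a fitted finite endpoint gives sf=0
        out[hi] = np.clip(tail_mass * sf, 1e-16, 1.0)
    return out


# --------------------------------------------------------------------------
# test result container


@dataclass
class TestResult:
    """Per-unit permutation test result (units are regions or networks)."""

    units: pd.Index
    observed: np.ndarray
    p_unc: np.ndarray          # two-tailed
    p_fdr_flags: np.ndarray    # BH at q
    sig_unc: np.ndarray
    null_model: str
    q: float = 0.05
    alpha_unc: float = 0.05
    null: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta": self.observed, "p_unc": self.p_unc,
             "sig_unc": self.sig_unc, "sig_fdr": self.p_fdr_flags,
             "null_model": self.null_model},
            index=self.units.rename("unit"))

    def write(self, path, sign: str = "") -> None:
        out = self.to_frame()
        if sign:
            out.insert(0, "sign", sign)
        out.to_csv(path, sep="\t")


def _two_tailed(null: np.ndarray, observed: np.ndarray, gpd: bool,
                seed: int) -> np.ndarray:
    """Two-tailed p per unit from a null sample [n_perm x U]:
    p = min(1, 2 min(p_upper, p_lower)) with GPD-refined one-sided tails."""
    n_perm, n_units = null.shape
    p_up = (1.0 + (null >= observed[None, :]).sum(axis=0)) / (n_perm + 1.0)
    p_lo = (1.0 + (null <= observed[None, :]).sum(axis=0)) / (n_perm + 1.0)
    if gpd and n_perm >= 100:
        for u in range(n_units):
            if p_up[u] < 0.10:
                p_up[u] = gpd_tail_pvalue(null[:, u], observed[u], seed=seed + 2 * u)
            elif p_lo[u] < 0.10:
                p_lo[u] = gpd_tail_pvalue(-null[:, u], -observed[u], seed=seed + 2 * u + 1)
    return np.minimum(1.0, 2.0 * np.minimum(p_up, p_lo))


def _finalize(units, observed, null, null_model, q, alpha_unc, gpd, seed,
              keep_null) -> TestResult:
    p = _two_tailed(null, observed, gpd, seed)
    sig_unc = p < alpha_unc
    flags = fdr_correct(p, q) & sig_unc  # FDR flags are a subset of uncorrected flags
    return TestResult(pd.Index(units), observed, p, flags, sig_unc, null_model,
                      q, alpha_unc, null if keep_null else None)


# --------------------------------------------------------------------------
# group-label permutation


def _null_mean_diff(scores: np.ndarray, n_case: int, n_perm: int,
                    rng: np.random.Generator, chunk: int = 256) -> np.ndarray:
    """Null mean-difference sample by shuffling group labels (vectorised)."""
    n, _ = scores.shape
    n_ctrl = n - n_case
    out = np.empty((n_perm, scores.shape[1]), dtype=float)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        order = np.argsort(rng.random((m, n)), axis=1)
        ind = np.zeros((m, n))
        np.put_along_axis(ind, order[:, :n_case], 1.0, axis=1)
        out[done:done + m] = ind @ scores / n_case - (1.0 - ind) @ scores / n_ctrl
        done += m
    return out


def group_permutation_test(case_scores, control_scores, n_perm: int = 10_000,
                           seed: int = 0, q: float = 0.05, alpha_unc: float = 0.05,
                           gpd: bool = True, keep_null: bool = False,
                           units=None) -> TestResult:
    """Two-tailed group-label permutation test of the per-unit difference in
    group means (Δ-overlap when the scores are extreme/circuit indicators)."""
    case = np.atleast_2d(np.asarray(case_scores, dtype=float))
    ctrl = np.atleast_2d(np.asarray(control_scores, dtype=float))
    if case.shape[0] == 0 or ctrl.shape[0] == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
    if units is None:
        units = (case_scores.columns if isinstance(case_scores, pd.DataFrame)
                 else pd.RangeIndex(case.shape[1]))
    scores = np.vstack([case, ctrl])
    observed = case.mean(axis=0) - ctrl.mean(axis=0)
    rng = np.random.default_rng(seed)
    null = _null_mean_diff(scores, case.shape[0], n_perm, rng)
    return _finalize(units, observed, null, "group", q, alpha_unc, gpd, seed, keep_null)


def permutation_mean_difference_p(x: np.ndarray, y: np.ndarray,
                                  n_perm: int = 10_000, seed: int = 0,
                                  exact_limit: int = 20_000) -> float:
    """One-sided (x > y) permutation p for the difference in means.

    Exhaustive enumeration over all group assignments when their number does
    not exceed ``exact_limit``; Monte Carlo with the add-one estimator
    otherwise.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    obs = x.mean() - y.mean()
    if math.comb(n, n1) <= exact_limit:
        count = total = 0
        for idx in combinations(range(n), n1):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            d = pooled[sel].mean() - pooled[~sel].mean()
            count += d >= obs - 1e-12
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    null = _null_mean_diff(pooled[:, None], n1, n_perm, rng)[:, 0]
    return float((1.0 + (null >= obs - 1e-12).sum()) / (n_perm + 1.0))


# --------------------------------------------------------------------------
# spherical spin permutations (Hungarian assignment)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q


def _assign(coords: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Cost-minimising bijection after rotating ``coords``; returns π with
    surrogate[j] = original[π[j]]."""
    rotated = coords @ rotation.T
    cost = -rotated @ coords.T  # maximise cosine similarity
    rows, cols = linear_sum_assignment(cost)
    pi = np.empty(len(coords), dtype=int)
    pi[cols[rows]] = rows
    return pi


def spin_rotation_assignment(coords_left: np.ndarray, coords_right: np.ndarray,
                             seed: int | None = None,
                             rotation: np.ndarray | None = None) -> np.ndarray:
    """Bijective spin permutation over [left; right] cortical regions.

    One rotation is drawn (or supplied); it is applied to the left hemisphere
    and its x-mirror to the right so that homotopy is preserved.  Region values
    are reassigned by Hungarian matching between rotated and original
    positions, so every value is used exactly once.
    """
    coords_left = np.asarray(coords_left, dtype=float)
    coords_right = np.asarray(coords_right, dtype=float)
    if len(coords_left) != len(coords_right):
        raise ValueError("hemispheres must have equal numbers of regions")
    if rotation is None:
        rotation = random_rotation(np.random.default_rng(seed))
    n = len(coords_left)
    pi_l = _assign(coords_left, rotation)
    # mirror the right hemisphere into the left frame, spin, mirror back
    pi_r = _assign(coords_right @ _MIRROR.T, rotation)
    return np.concatenate([pi_l, pi_r + n])


def spin_permutation_pool(scheme, n_perm: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """(cortical positions in scheme order, pool [n_perm x n_cortex] of spin
    permutations expressed over those positions)."""
    ids_l, coords_l = scheme.cortical_coords("L")
    ids_r, coords_r = scheme.cortical_coords("R")
    region_ids = scheme.region_ids
    pos = {rid: i for i, rid in enumerate(region_ids)}
    cpos = np.array([pos[r] for r in np.concatenate([ids_l, ids_r])])
    rng = np.random.default_rng(seed)
    pool = np.empty((n_perm, len(cpos)), dtype=np.int32)
    for k in range(n_perm):
        pool[k] = spin_rotation_assignment(coords_l, coords_r,
                                           rotation=random_rotation(rng))
    return cpos, pool


# --------------------------------------------------------------------------
# spatial null model


def _surrogate_index(cpos, spos, pool, draws, rng) -> np.ndarray:
    """Per-subject full-region source-index matrix for one permutation."""
    n_subj = len(draws)
    n_regions = len(cpos) + len(spos)
    idx = np.tile(np.arange(n_regions, dtype=np.int64), (n_subj, 1))
    idx[:, cpos] = cpos[pool[draws]]
    if len(spos):
        shuf = np.argsort(rng.random((n_subj, len(spos))), axis=1)
        idx[:, spos] = spos[shuf]
    return idx


def spatial_null_test(z: pd.DataFrame, scheme, case_mask, control_mask,
                      downstream: str = "regional", sign: str = "negative",
                      z_thr: float = 2.6, circuit_matrix: np.ndarray | None = None,
                      network_membership: np.ndarray | None = None,
                      network_names=None, n_perm: int = 10_000, seed: int = 0,
                      q: float = 0.05, alpha_unc: float = 0.05, gpd: bool = True,
                      weighted_range: tuple = (1.64, 3.10, 100),
                      keep_null: bool = False) -> TestResult:
    """Spatial (spin) permutation test of group Δ-overlap.

    Each permutation rotates every subject's cortical deviation values
    (independent draws from a pool of Hungarian spin permutations), shuffles
    subcortical values per subject, re-thresholds at ``z_thr`` and rebuilds the
    downstream statistic: ``regional`` (extreme-deviation overlap), ``circuit``
    (union of cached seed circuits), ``network`` (network deviance) or
    ``weighted`` (threshold-weighted survival score, a continuous statistic).
    Every surrogate preserves each subject's deviation burden exactly.
    """
    region_ids = scheme.region_ids
    z = z.loc[:, region_ids]
    case_mask = np.asarray(case_mask, dtype=bool)
    control_mask = np.asarray(control_mask, dtype=bool)
    if case_mask.sum() == 0 or control_mask.sum() == 0:
        raise ValueError("both groups must be nonempty")

    is_cortex = scheme.is_cortex()
    spos = np.flatnonzero(~is_cortex)
    rng = np.random.default_rng(seed)
    cpos, pool = spin_permutation_pool(scheme, n_perm, seed=int(rng.integers(2**31)))

    if downstream == "weighted":
        feat = weighted_survival_scores(z, sign, *weighted_range).to_numpy()
    else:
        feat = extremes_for_sign(z, sign, z_thr).to_numpy()
    feat = feat.astype(np.float32)

    if downstream in ("regional", "regional-burden", "weighted"):
        transform = lambda f: f
        units = pd.Index(region_ids)
    elif downstream == "circuit":
        if circuit_matrix is None:
            raise ValueError("downstream='circuit' requires a circuit matrix")
        C = np.asarray(circuit_matrix, dtype=np.float32)
        transform = lambda f: (f @ C > 0.5).astype(np.float32)
        units = pd.Index(region_ids)
    elif downstream == "network":
        if network_membership is None:
            raise ValueError("downstream='network' requires a membership matrix")
        M = np.asarray(network_membership, dtype=np.float32)
        transform = lambda f: (f @ M > 0.5).astype(np.float32)
        units = pd.Index(network_names if network_names is not None
                         else np.arange(M.shape[1]))
    else:
        raise ValueError(f"unknown downstream {downstream!r}")

    def delta(f):
        t = transform(f)
        return t[case_mask].mean(axis=0) - t[control_mask].mean(axis=0)

    observed = delta(feat)
    n_subj = feat.shape[0]
    null = np.empty((n_perm, len(units)), dtype=float)
    for k in range(n_perm):
        draws = rng.integers(0, n_perm, size=n_subj)
        idx = _surrogate_index(cpos, spos, pool, draws, rng)
        null[k] = delta(np.take_along_axis(feat, idx, axis=1))
    return _finalize(units, observed, null, "spatial", q, alpha_unc, gpd, seed, keep_null)


# --------------------------------------------------------------------------
# cross-scale contrast


def crossscale_contrast(extremes: pd.DataFrame, union_maps: pd.DataFrame,
                        case_mask, control_mask, n_perm: int = 10_000,
                        seed: int = 0, q: float = 0.05, alpha_unc: float = 0.05,
                        gpd: bool = True, keep_null: bool = False) -> TestResult:
    """Per-region (Δ circuit-overlap − Δ regional-overlap), with group-label
    permutation recomputing both levels per shuffle."""
    if not extremes.columns.equals(union_maps.columns) or \
       not extremes.index.equals(union_maps.index):
        raise ValueError("extreme and union maps must share subjects and regions")
    case_mask = np.asarray(case_mask, dtype=bool)
    control_mask = np.asarray(control_mask, dtype=bool)
    E = extremes.to_numpy().astype(float)
    U = union_maps.to_numpy().astype(float)
    both = np.hstack([U, E])
    n_case = int(case_mask.sum())
    scores = np.vstack([both[case_mask], both[control_mask]])
    R = E.shape[1]
    obs = (both[case_mask].mean(axis=0) - both[control_mask].mean(axis=0))
    observed = obs[:R] - obs[R:]
    rng = np.random.default_rng(seed)
    null_both = _null_mean_diff(scores, n_case, n_perm, rng)
    null = null_both[:, :R] - null_both[:, R:]
    return _finalize(extremes.columns, observed, null, "group", q, alpha_unc,
                     gpd, seed, keep_null)


# --------------------------------------------------------------------------
# spatial autocorrelation diagnostic


def moran_i(values: np.ndarray, coords: np.ndarray, k: int = 6) -> float:
    """Moran's I with symmetrised binary k-NN weights (spin-test diagnostic)."""
    values = np.asarray(values, dtype=float)
    zc = values - values.mean()
    n = len(values)
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=min(k, n - 1) + 1)
    W = np.zeros((n, n))
    for i in range(n):
        W[i, idx[i, 1:]] = 1.0
    W = np.maximum(W, W.T)
    return float((n / W.sum()) * (zc @ W @ zc) / (zc @ zc))
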