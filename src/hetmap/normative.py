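"""Hierarchical normative model of regional phenotypes.

Per region, the (Box–Cox transformed) phenotype is modelled linearly in age
with batch-specific intercept, slope and noise, where a batch is a
(site, sex) cell.  Batch parameters are partially pooled: each batch is fitted
by maximum likelihood and then shrunk toward hyperpriors whose location and
spread are estimated across batches by method of moments (an empirical-Bayes
two-stage approximation to a full hierarchical Bayesian fit; the contract is
calibrated predictions ŷ, predictive uncertainty σ_ij and normative variance
σ_nj, which the calibration tests verify).

A subject's deviation is scored as

    z_ij = (y_ij − ŷ_ij) / sqrt(σ_ij² + σ_nj²)

where σ_ij is the epistemic standard error of the prediction and σ_nj the
modelled population (aleatoric) standard deviation at the prediction point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .cohort import CohortTable

DEFAULT_Z_THRESHOLD = 2.6


# --------------------------------------------------------------------------
# Box–Cox


def boxcox_transform(x: np.ndarray, lam: float) -> np.ndarray:
    """((x**lam - 1)/lam) for lam != 0, log(x) for lam == 0."""
    x = np.asarray(x, dtype=float)
    if abs(lam) < 1e-12:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def boxcox_fit_apply(values: np.ndarray, name: str | None = None,
                     bounds: tuple[float, float] = (-2.0, 2.0)) -> tuple[float, np.ndarray]:
    """Maximum-likelihood Box–Cox lambda (bounded search) and transformed values.

    Near-flat profiles are tied toward lambda = 1 (no transformation).
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        where = f" in region {name}" if name is not None else ""
        raise ValueError(f"Box–Cox requires strictly positive values{where}")
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, values), bounds=bounds, method="bounded")
    lam = float(res.x)
    if stats.boxcox_llf(1.0, values) >= -res.fun - 1e-8:
        lam = 1.0
    return lam, boxcox_transform(values, lam)


# --------------------------------------------------------------------------
# train/test split


def split_train_test(
    cohort: CohortTable,
    train_frac: float = 0.9,
    site_min_for_split: int = 30,
    min_batch: int = 10,
    seed: int = 0,
) -> tuple[CohortTable, CohortTable]:
    """Stratify a cohort into training controls and a test set (held-out
    controls plus all cases).

    Rules: (site, sex) cells with fewer than ``min_batch`` controls are dropped
    entirely (controls and cases); a site that loses cells and retains fewer
    than ``min_batch`` cases (among sites that had cases) is dropped wholly;
    sites with >= ``site_min_for_split`` controls contribute ``1 - train_frac``
    of them (rounded) to the test set, smaller sites contribute all controls to
    training.
    """
    rng = np.random.default_rng(seed)
    sub = cohort.subjects
    is_case = cohort.is_case()
    is_hc = sub["group"].isin(["HC", "HC_train", "HC_test"])
    if not is_hc.any():
        raise ValueError("cohort has no control rows")

    keep = pd.Series(True, index=sub.index)
    dropped_cell_sites = set()
    for (site, sex), cell in sub.groupby(["site", "sex"]):
        n_hc = int((is_hc & (sub["site"] == site) & (sub["sex"] == sex)).sum())
        if n_hc < min_batch:
            keep[cell.index] = False
            dropped_cell_sites.add(site)
    for site in dropped_cell_sites:
        site_rows = sub["site"] == site
        had_cases = int((is_case & site_rows).sum())
        n_cases_left = int((is_case & site_rows & keep).sum())
        if had_cases and n_cases_left < min_batch:
            keep[site_rows] = False

    sub = sub[keep]
    if sub.empty or not (is_hc & keep).any():
        raise ValueError("no site survives the batch-exclusion rules")

    train_ids, test_ids = [], []
    for site, site_sub in sub.groupby("site"):
        hc_ids = site_sub.index[is_hc[site_sub.index]].to_numpy()
        n = len(hc_ids)
        if n >= site_min_for_split:
            n_train = int(np.floor(train_frac * n + 0.5))
            perm = rng.permutation(n)
            train_ids.extend(hc_ids[perm[:n_train]])
            test_ids.extend(hc_ids[perm[n_train:]])
        else:
            train_ids.extend(hc_ids)
        test_ids.extend(site_sub.index[is_case[site_sub.index]])

    train = cohort.select(cohort.subjects.index.isin(train_ids))
    test = cohort.select(cohort.subjects.index.isin(test_ids))
    train.subjects.loc[:, "group"] = "HC_train"
    test.subjects.loc[:, "group"] = test.subjects["group"].replace(
        {"HC": "HC_test", "HC_train": "HC_test"})
    return train, test


# --------------------------------------------------------------------------
# model fit


@dataclass
class NormativeModelFit:
    """Fitted per-region, per-batch normative model (empirical-Bayes backend)."""

    region_ids: np.ndarray
    batches: list                # list of (site, sex) tuples
    lambdas: np.ndarray          # (R,)
    age_center: float
    intercept: np.ndarray        # (R, B) shrunk
    slope: np.ndarray            # (R, B) shrunk
    se_intercept: np.ndarray     # (R, B) posterior SD of the shrunk intercept
    se_slope: np.ndarray         # (R, B)
    sigma: np.ndarray            # (R, B) normative (residual) SD
    hyper: dict = field(default_factory=dict)
    train_stats: dict = field(default_factory=dict)  # per-region mean/var on transformed scale

    def batch_index(self, sites, sexes) -> np.ndarray:
        lut = {b: i for i, b in enumerate(self.batches)}
        out = np.empty(len(sites), dtype=int)
        for i, key in enumerate(zip(sites, sexes)):
            if key not in lut:
                raise KeyError(f"batch {key} was not present in the training data")
            out[i] = lut[key]
        return out

    # -------------------------------------------------------------- persist
    def to_json(self, path: str | Path) -> None:
        payload = dict(
            region_ids=self.region_ids.tolist(),
            batches=[list(b) for b in self.batches],
            lambdas=self.lambdas.tolist(),
            age_center=self.age_center,
            intercept=self.intercept.tolist(), slope=self.slope.tolist(),
            se_intercept=self.se_intercept.tolist(), se_slope=self.se_slope.tolist(),
            sigma=self.sigma.tolist(), hyper=self.hyper,
            train_stats={k: np.asarray(v).tolist() for k, v in self.train_stats.items()},
        )
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeModelFit":
        d = json.loads(Path(path).read_text())
        return cls(
            region_ids=np.asarray(d["region_ids"]),
            batches=[tuple(b) for b in d["batches"]],
            lambdas=np.asarray(d["lambdas"]), age_center=d["age_center"],
            intercept=np.asarray(d["intercept"]), slope=np.asarray(d["slope"]),
            se_intercept=np.asarray(d["se_intercept"]), se_slope=np.asarray(d["se_slope"]),
            sigma=np.asarray(d["sigma"]), hyper=d.get("hyper", {}),
            train_stats={k: np.asarray(v) for k, v in d.get("train_stats", {}).items()},
        )


def _shrink(est: np.ndarray, se2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Empirical-Bayes shrinkage of per-batch estimates toward their grand mean.

    The between-batch variance tau² is estimated by method of moments with the
    signal-to-sampling ratio *pooled across regions* (the shared-hyperprior
    step): per region, (var of batch estimates − mean sampling variance) /
    mean sampling variance; the across-region mean of this unclipped ratio is
    floored at zero and rescaled by each region's sampling variance.  Pooling
    before flooring removes the positive bias that per-region flooring would
    introduce, so truly identical batches shrink (essentially) all the way to
    the grand mean.  Returns (shrunk estimates, posterior SDs, mu, tau²);
    arrays are (R, B).
    """
    mu = est.mean(axis=1, keepdims=True)
    mean_se2 = se2.mean(axis=1, keepdims=True)
    ratio = (est.var(axis=1, ddof=1, keepdims=True) - mean_se2) / mean_se2
    tau2 = np.maximum(ratio.mean(), 0.0) * mean_se2 + 1e-12
    w = 1.0 / se2
    w0 = 1.0 / tau2
    post = (est * w + mu * w0) / (w + w0)
    post_sd = np.sqrt(1.0 / (w + w0))
    return post, post_sd, mu, tau2


def fit_normative(
    train: CohortTable,
    min_batch: int = 10,
    prior_dof: float = 10.0,
) -> NormativeModelFit:
    """Fit the per-region hierarchical model on training controls.

    ``prior_dof`` is the pseudo-count of the inverse-gamma-style pooling of the
    batch noise variances toward their across-batch mean.
    """
    sub = train.subjects
    y_raw = train.phenotype.to_numpy()
    region_ids = train.region_ids
    R = len(region_ids)

    batch_key = list(zip(sub["site"], sub["sex"]))
    batches = sorted(set(batch_key))
    if len(batches) < 2:
        raise ValueError("need >= 2 (site, sex) batches to fit the hierarchical model")
    b_index = np.array([batches.index(k) for k in batch_key])
    for b, key in enumerate(batches):
        if (b_index == b).sum() < min_batch:
            raise ValueError(f"batch {key} has fewer than {min_batch} training subjects")

    lambdas = np.empty(R)
    Y = np.empty_like(y_raw)
    for j, rid in enumerate(region_ids):
        lambdas[j], Y[:, j] = boxcox_fit_apply(y_raw[:, j], name=str(rid))

    age_center = float(sub["age"].mean())
    age_c = sub["age"].to_numpy() - age_center

    B = len(batches)
    a_hat = np.empty((R, B)); m_hat = np.empty((R, B))
    se_a2 = np.empty((R, B)); se_m2 = np.empty((R, B))
    s2 = np.empty((R, B)); dof = np.empty(B)
    for b, key in enumerate(batches):
        rows = np.flatnonzero(b_index == b)
        yb = Y[rows]
        if np.ptp(yb, axis=0).min() == 0 and np.allclose(yb.var(axis=0).min(), 0):
            j = int(np.argmin(yb.var(axis=0)))
            raise ValueError(
                f"degenerate batch {key}: zero phenotype variance in region {region_ids[j]}")
        x = age_c[rows]
        if np.ptp(x) == 0:
            raise ValueError(f"degenerate batch {key}: no age variation")
        X = np.column_stack([np.ones(len(rows)), x])
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ (X.T @ yb)          # (2, R)
        resid = yb - X @ beta
        nb = len(rows)
        dof[b] = max(nb - 2, 1)
        s2[:, b] = (resid**2).sum(axis=0) / dof[b]
        a_hat[:, b] = beta[0]; m_hat[:, b] = beta[1]
        se_a2[:, b] = np.maximum(s2[:, b] * xtx_inv[0, 0], 1e-18)
        se_m2[:, b] = np.maximum(s2[:, b] * xtx_inv[1, 1], 1e-18)

    a_post, a_sd, mu_a, tau2_a = _shrink(a_hat, se_a2)
    m_post, m_sd, mu_m, tau2_m = _shrink(m_hat, se_m2)
    # partial pooling of log-variances toward the across-batch mean
    s2_pool = s2.mean(axis=1, keepdims=True)
    s2_post = (dof[None, :] * s2 + prior_dof * s2_pool) / (dof[None, :] + prior_dof)
    sigma = np.sqrt(np.maximum(s2_post, 1e-18))

    return NormativeModelFit(
        region_ids=region_ids, batches=batches, lambdas=lambdas,
        age_center=age_center,
        intercept=a_post, slope=m_post,
        se_intercept=a_sd, se_slope=m_sd, sigma=sigma,
        hyper=dict(mu_intercept=mu_a.ravel().tolist(), tau2_intercept=tau2_a.ravel().tolist(),
                   mu_slope=mu_m.ravel().tolist(), tau2_slope=tau2_m.ravel().tolist(),
                   prior_dof=prior_dof),
        train_stats=dict(mean=Y.mean(axis=0), var=Y.var(axis=0, ddof=1)),
    )


@dataclass
class NormativePrediction:
    """Per subject x region predictions on the transformed scale."""

    y: pd.DataFrame        # observed (transformed)
    y_hat: pd.DataFrame
    sigma_pred: pd.DataFrame   # epistemic SE of y_hat (σ_ij)
    sigma_norm: pd.DataFrame   # normative SD (σ_nj, batch-specific)


def predict_normative(fit: NormativeModelFit, cohort: CohortTable) -> NormativePrediction:
    if not np.array_equal(cohort.region_ids, fit.region_ids):
        raise ValueError("cohort regions do not match the fitted model")
    sub = cohort.subjects
    b = fit.batch_index(sub["site"], sub["sex"])
    age_c = sub["age"].to_numpy() - fit.age_center
    y_raw = cohort.phenotype.to_numpy()
    Y = np.empty_like(y_raw, dtype=float)
    for j, lam in enumerate(fit.lambdas):
        Y[:, j] = boxcox_transform(y_raw[:, j], lam)
    y_hat = fit.intercept[:, b].T + fit.slope[:, b].T * age_c[:, None]
    s_ij = np.sqrt(fit.se_intercept[:, b].T**2 + (fit.se_slope[:, b].T * age_c[:, None])**2)
    s_nj = fit.sigma[:, b].T
    idx, cols = cohort.phenotype.index, cohort.phenotype.columns
    wrap = lambda arr: pd.DataFrame(arr, index=idx, columns=cols)
    return NormativePrediction(wrap(Y), wrap(y_hat), wrap(s_ij), wrap(s_nj))


# --------------------------------------------------------------------------
# deviation scores


def deviation_z(y, y_hat, sigma_pred, sigma_norm):
    """z = (y − ŷ)/sqrt(σ_ij² + σ_nj²); scale-equivariant, antisymmetric in y−ŷ."""
    y, y_hat = np.asarray(y, dtype=float), np.asarray(y_hat, dtype=float)
    s_ij, s_nj = np.asarray(sigma_pred, dtype=float), np.asarray(sigma_norm, dtype=float)
    if np.any(s_ij < 0):
        raise ValueError("sigma_pred must be >= 0")
    denom2 = s_ij**2 + s_nj**2
    if np.any(denom2 <= 0):
        raise ZeroDivisionError("sigma_pred and sigma_norm cannot both be zero")
    return (y - y_hat) / np.sqrt(denom2)


@dataclass
class DeviationMap:
    """Per-subject deviation z maps with extreme-deviation indicators."""

    z: pd.DataFrame
    z_thr: float
    groups: pd.Series

    @property
    def pos_extreme(self) -> pd.DataFrame:
        return self.z > self.z_thr

    @property
    def neg_extreme(self) -> pd.DataFrame:
        return self.z < -self.z_thr

    def write(self, path: str | Path) -> None:
        out = self.z.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, sep="\t", index=True, index_label="subject_id")


def deviation_map(fit: NormativeModelFit, cohort: CohortTable,
                  z_thr: float = DEFAULT_Z_THRESHOLD) -> DeviationMap:
    pred = predict_normative(fit, cohort)
    z = deviation_z(pred.y, pred.y_hat, pred.sigma_pred, pred.sigma_norm)
    return DeviationMap(pd.DataFrame(z, index=pred.y.index, columns=pred.y.columns),
                        z_thr, cohort.subjects["group"].copy())


# --------------------------------------------------------------------------
# model-fit metrics


def fit_metrics(y: np.ndarray, y_hat: np.ndarray, pred_var: np.ndarray,
                train_mean: np.ndarray, train_var: np.ndarray) -> pd.DataFrame:
    """Explained variance, standardized MSE and mean standardized log-loss,
    per region (columns of the inputs).

    SMSE standardizes by the training-mean predictor; MSLL subtracts the
    log-loss of the trivial Gaussian predictor with training mean/variance,
    so negative MSLL is better and the trivial predictor scores 0.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=float))
    pred_var = np.atleast_2d(np.asarray(pred_var, dtype=float))
    if y.shape[0] < 2:
        raise ValueError("fit_metrics requires >= 2 test subjects")
    resid = y - y_hat
    var_y = y.var(axis=0)
    flagged = var_y <= 1e-30
    with np.errstate(divide="ignore", invalid="ignore"):
        ev = 1.0 - resid.var(axis=0) / var_y
        mse = (resid**2).mean(axis=0)
        mse0 = ((y - train_mean)**2).mean(axis=0)
        smse = mse / mse0
        ll = 0.5 * np.log(2 * np.pi * pred_var) + resid**2 / (2 * pred_var)
        ll0 = 0.5 * np.log(2 * np.pi * train_var) + (y - train_mean)**2 / (2 * train_var)
        msll = (ll - ll0).mean(axis=0)
    ev[flagged] = np.nan; smse[flagged] = np.nan
    return pd.DataFrame({"EV": ev, "SMSE": smse, "MSLL": msll, "flagged": flagged})


def metrics_from_prediction(pred: NormativePrediction, fit: NormativeModelFit) -> pd.DataFrame:
    pv = pred.sigma_pred.to_numpy()**2 + pred.sigma_norm.to_numpy()**2
    out = fit_metrics(pred.y.to_numpy(), pred.y_hat.to_numpy(), pv,
                      fit.train_stats["mean"], fit.train_stats["var"])
    out.index = fit.region_ids
    return out


# --------------------------------------------------------------------------
# site-leakage diagnostic


def site_leakage_score(
    z_maps: np.ndarray | pd.DataFrame,
    site_labels,
    folds: int = 2,
    slack: float = 1.0,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict:
    """One-versus-all linear-SVM site classification of deviation z maps.

    For each site, a linear SVM (C = ``slack``) is trained/tested over
    stratified ``folds``-fold splits, repeated ``n_repeats`` times with
    different fold seeds; the per-site score is the mean balanced accuracy.
    Chance level (0.5) indicates no residual site leakage.
    """
    X = np.asarray(z_maps, dtype=float)
    site_labels = np.asarray(site_labels)
    sites = np.unique(site_labels)
    if len(sites) < 2:
        raise ValueError("need >= 2 sites")
    per_site = {}
    for site in sites:
        y = (site_labels == site).astype(int)
        if y.sum() < folds or (len(y) - y.sum()) < folds:
            warnings.warn(f"site {site!r} too small for {folds}-fold CV; skipped")
            continue
        scores = []
        for rep in range(n_repeats):
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
            for tr, te in skf.split(X, y):
                if len(np.unique(y[tr])) < 2:
                    warnings.warn(f"fold without both classes for site {site!r}; skipped")
                    continue
                clf = SVC(kernel="linear", C=slack)
                clf.fit(X[tr], y[tr])
                scores.append(balanced_accuracy_score(y[te], clf.predict(X[te])))
        per_site[site] = float(np.mean(scores))
    return dict(per_site=per_site, mean=float(np.mean(list(per_site.values()))))


# --------------------------------------------------------------------------
# cross-validation


def crossval_evaluate(train: CohortTable, k: int = 5, seed: int = 0,
                      min_batch: int = 2) -> dict:
    """Stratified k-fold cross-validation of the normative model on controls.

    Folds are stratified by (site, sex) batch; batches too small to stratify
    fall back to pooled random assignment with a warning.  Every subject is
    predicted exactly once.  Returns per-fold metric tables and the per-subject
    fold assignment.
    """
    rng = np.random.default_rng(seed)
    sub = train.subjects
    n = len(sub)
    fold_of = np.full(n, -1, dtype=int)
    batch_key = np.array([f"{s}|{x}" for s, x in zip(sub["site"], sub["sex"])])
    for key in np.unique(batch_key):
        rows = np.flatnonzero(batch_key == key)
        if len(rows) < k:
            warnings.warn(f"batch {key} smaller than k={k}; pooled random fold assignment")
        perm = rng.permutation(rows)
        # round-robin from a random offset: no fold ever swallows a whole batch
        fold_of[perm] = (int(rng.integers(k)) + np.arange(len(perm))) % k
    folds = []
    for f in range(k):
        te = fold_of == f
        fit = fit_normative(train.select(~te), min_batch=min_batch)
        pred = predict_normative(fit, train.select(te))
        folds.append(metrics_from_prediction(pred, fit))
    return dict(metrics=folds, fold_of=pd.Series(fold_of, index=sub.index))
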