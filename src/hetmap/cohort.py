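"""Synthetic multi-site phenotype cohorts and case-deviation injection.

Phenotypes are gray-matter-volume-like: strictly positive, generated on the log
scale as ``exp(baseline_j + age_slope*age + sex_offset*1[M] + site_offset + eps)``
with site-specific Gaussian noise, so the Box–Cox step of the normative model has
real work to do (the maximising lambda is ~0).  Case deviations are injected in
z units via the generator's own noise scale, which makes detection probability
controllable: shifting the log-phenotype by ``effect_size * site_noise_scale``
moves the expected normative z score by ``effect_size``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .parcellation import ParcellationScheme

COVARIATE_COLUMNS = ["subject_id", "age", "sex", "site", "group"]


@dataclass
class CohortTable:
    """Subjects x regions phenotype matrix plus per-subject covariates."""

    subjects: pd.DataFrame  # columns: subject_id, age, sex, site, group (indexed by subject_id)
    phenotype: pd.DataFrame  # index: subject_id, columns: region_id (ints)
    gen_params: dict = field(default_factory=dict)  # generator ground truth, if synthetic

    def __post_init__(self):
        if not self.subjects.index.equals(self.phenotype.index):
            raise ValueError("subjects and phenotype must share the same subject index")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def region_ids(self) -> np.ndarray:
        return np.asarray(self.phenotype.columns, dtype=int)

    def validate(self) -> None:
        for col in ("age", "sex", "site", "group"):
            if self.subjects[col].isna().any():
                bad = self.subjects.index[self.subjects[col].isna()][0]
                raise ValueError(f"missing covariate {col!r} for subject {bad!r}")
        vals = self.phenotype.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            i, j = np.argwhere(~(np.isfinite(vals) & (vals > 0)))[0]
            raise ValueError(
                f"phenotype must be strictly positive and finite; offending entry "
                f"subject {self.phenotype.index[i]!r}, region {self.phenotype.columns[j]}"
            )

    def select(self, mask: np.ndarray | pd.Series) -> "CohortTable":
        return CohortTable(self.subjects.loc[mask].copy(), self.phenotype.loc[mask].copy(),
                           dict(self.gen_params))

    def is_case(self) -> pd.Series:
        return self.subjects["group"].str.startswith("case:")

    # ------------------------------------------------------------------ I/O
    def write(self, path: str | Path) -> None:
        out = self.subjects.copy()
        for rid in self.phenotype.columns:
            out[f"region_{rid}"] = self.phenotype[rid]
        out.reset_index(drop=True).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        df = df.set_index("subject_id", drop=False)
        region_cols = [c for c in df.columns if c.startswith("region_")]
        phen = df[region_cols].copy()
        phen.columns = [int(c.split("_", 1)[1]) for c in region_cols]
        cohort = cls(df[COVARIATE_COLUMNS].copy(), phen)
        cohort.validate()
        return cohort


# --------------------------------------------------------------------------
# burden distributions


@dataclass(frozen=True)
class ZeroInflatedPoisson:
    """Number of extreme seeds per case: 0 with probability ``pi``, else
    Poisson with rate ``mean / (1 - pi)`` so that the marginal mean is ``mean``."""

    mean: float = 6.0
    pi: float = 0.1

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lam = self.mean / (1.0 - self.pi)
        k = rng.poisson(lam, size=n)
        k[rng.random(n) < self.pi] = 0
        return k


@dataclass(frozen=True)
class FixedBurden:
    """Degenerate burden distribution: every case receives exactly ``k`` seeds."""

    k: int = 1

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, self.k, dtype=int)


@dataclass(frozen=True)
class DeviationScenario:
    """Configuration of injected case deviations.

    kind:
        ``null`` (no injection), ``burden_only`` (seed regions uniform at
        random), ``circuit_convergent`` (seeds preferentially among regions
        whose normative coupling to ``hub_set`` exceeds its 80th percentile)
        or ``region_focal`` (seeds from a fixed small region list).
    effect_size:
        Expected |z| of the injected deviation at seeded regions (>= 0).
    sign:
        -1 for deficits (default, lower-than-expected volume), +1 for excesses.
    """

    kind: str
    burden_distribution: object = ZeroInflatedPoisson()
    effect_size: float = 4.0
    hub_set: tuple = ()
    region_list: tuple = ()
    sign: int = -1
    seed: int = 0

    def __post_init__(self):
        if self.kind not in {"null", "burden_only", "circuit_convergent", "region_focal"}:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if (self.kind == "circuit_convergent") != bool(len(self.hub_set)):
            raise ValueError("hub_set must be nonempty iff kind == 'circuit_convergent'")
        if self.kind == "region_focal" and not self.region_list:
            raise ValueError("region_focal requires a region_list")


# --------------------------------------------------------------------------


def make_cohort(
    scheme: ParcellationScheme,
    site_spec: Sequence[tuple],
    age_range: tuple[float, float] = (18.0, 64.0),
    effects: dict | None = None,
    seed: int = 0,
) -> CohortTable:
    """Generate a multi-site control + case cohort with known ground truth.

    ``site_spec`` is a sequence of ``(site, n_HC, n_case_per_dx)`` where
    ``n_case_per_dx`` is either an int (a single diagnosis ``dx1``) or a dict
    ``{dx: n}``.  ``effects`` may override ``age_slope`` (log-units per year),
    ``sex_offset`` (log-units added for males), ``site_offsets`` (dict),
    ``site_noise_scales`` (dict) and ``baseline_sd``.  Unspecified site effects
    are drawn once from the generator's hyperdistributions.
    """
    if len(site_spec) < 1:
        raise ValueError("site_spec must name at least one site")
    if len(site_spec) < 2:
        warnings.warn("single-site cohort: site random effects are unidentifiable")

    rng = np.random.default_rng(seed)
    effects = dict(effects or {})
    age_slope = effects.get("age_slope", -0.004)
    sex_offset = effects.get("sex_offset", 0.08)
    baseline_sd = effects.get("baseline_sd", 0.4)

    region_ids = scheme.region_ids
    baselines = effects.get("baselines")
    if baselines is None:
        baselines = 6.5 + baseline_sd * rng.standard_normal(len(region_ids))
    baselines = np.asarray(baselines, dtype=float)

    sites = [s[0] for s in site_spec]
    site_offsets = dict(effects.get("site_offsets") or {})
    site_noise = dict(effects.get("site_noise_scales") or {})
    for s in sites:
        site_offsets.setdefault(s, float(rng.normal(0.0, 0.1)))
        site_noise.setdefault(s, float(rng.uniform(0.08, 0.15)))
        if site_noise[s] <= 0:
            raise ValueError(f"site_noise_scale for {s!r} must be > 0")

    rows, phen_rows = [], []
    counter = 1
    for site, n_hc, n_case in site_spec:
        if isinstance(n_case, int):
            n_case = {"dx1": n_case} if n_case else {}
        groups = ["HC"] * n_hc + [f"case:{dx}" for dx, n in n_case.items() for _ in range(n)]
        n = len(groups)
        ages = rng.uniform(age_range[0], age_range[1], size=n)
        sexes = np.array(["M", "F"] * (n // 2 + 1))[:n]
        rng.shuffle(sexes)
        eps = rng.normal(0.0, site_noise[site], size=(n, len(region_ids)))
        for i in range(n):
            sid = f"sub-{counter:05d}"
            counter += 1
            rows.append(dict(subject_id=sid, age=ages[i], sex=sexes[i], site=site,
                             group=groups[i]))
            eta = (baselines + age_slope * ages[i]
                   + (sex_offset if sexes[i] == "M" else 0.0)
                   + site_offsets[site] + eps[i])
            phen_rows.append(np.exp(eta))

    subjects = pd.DataFrame(rows).set_index("subject_id", drop=False)
    phenotype = pd.DataFrame(np.vstack(phen_rows), index=subjects.index,
                             columns=region_ids)
    cohort = CohortTable(
        subjects, phenotype,
        gen_params=dict(
            baselines=dict(zip(region_ids.tolist(), baselines.tolist())),
            age_slope=age_slope, sex_offset=sex_offset,
            site_offsets=site_offsets, site_noise_scales=site_noise,
            age_range=tuple(age_range), seed=seed,
        ),
    )
    cohort.validate()
    return cohort


def inject_case_deviations(
    cohort: CohortTable,
    scheme: ParcellationScheme,
    fc_reference: np.ndarray | None,
    scenario: DeviationScenario,
) -> CohortTable:
    """Shift case phenotypes at scenario-selected seed regions.

    Control rows are untouched.  The shift is applied multiplicatively on the
    raw scale (equivalently additively on the log scale) and scaled by the
    generating site noise so that the expected normative z at a seeded region
    equals ``scenario.sign * scenario.effect_size``.
    """
    if scenario.kind == "null":
        return CohortTable(cohort.subjects.copy(), cohort.phenotype.copy(),
                           dict(cohort.gen_params))

    rng = np.random.default_rng(scenario.seed)
    region_ids = cohort.region_ids
    n_regions = len(region_ids)
    pos = {rid: i for i, rid in enumerate(region_ids)}

    if scenario.kind == "circuit_convergent":
        fc_reference = np.asarray(fc_reference, dtype=float)
        if fc_reference.shape != (n_regions, n_regions):
            raise ValueError("fc_reference must be regions x regions")
        if not np.allclose(fc_reference, fc_reference.T, atol=1e-8):
            raise ValueError("fc_reference must be symmetric")
        hub_idx = np.array([pos[r] for r in scenario.hub_set])
        coupling = fc_reference[:, hub_idx].mean(axis=1)
        eligible = np.flatnonzero(coupling > np.quantile(coupling, 0.80))
    elif scenario.kind == "region_focal":
        eligible = np.array([pos[r] for r in scenario.region_list])
    else:  # burden_only
        eligible = np.arange(n_regions)

    noise = cohort.gen_params.get("site_noise_scales", {})
    phen = cohort.phenotype.to_numpy().copy()
    case_rows = np.flatnonzero(cohort.is_case().to_numpy())
    ks = scenario.burden_distribution.sample(rng, len(case_rows))
    for row, k in zip(case_rows, ks):
        if k <= 0:
            continue
        if scenario.kind == "burden_only":
            seeds = rng.choice(n_regions, size=min(k, n_regions), replace=False)
        else:
            seeds = rng.choice(eligible, size=min(k, len(eligible)), replace=False)
        site = cohort.subjects["site"].iloc[row]
        scale = noise.get(site, 0.1)
        phen[row, seeds] *= np.exp(scenario.sign * scenario.effect_size * scale)

    out = CohortTable(cohort.subjects.copy(),
                      pd.DataFrame(phen, index=cohort.phenotype.index,
                                   columns=cohort.phenotype.columns),
                      dict(cohort.gen_params))
    out.validate()
    return out
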