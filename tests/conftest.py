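"""Shared fixtures: small study objects for unit tests and two larger
session-scoped simulation bundles reused by the calibration/power suites."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import hetmap as h
from hetmap.fc_atlas import reference_coupling


@pytest.fixture(scope="session")
def small_scheme():
    return h.make_parcellation(40, 6, 3, seed=7)


@pytest.fixture(scope="session")
def labelled_scheme():
    """Large enough that every network label at both levels is populated."""
    return h.make_parcellation(100, 6, 3, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_scheme):
    return h.make_cohort(small_scheme, [("sA", 50, 12), ("sB", 50, 12), ("sC", 40, 12)],
                         seed=21)


@pytest.fixture(scope="session")
def small_fit(small_scheme, small_cohort):
    train, test = h.split_train_test(small_cohort, seed=31)
    fit = h.fit_normative(train, min_batch=5)
    dmap = h.deviation_map(fit, test)
    return dict(train=train, test=test, fit=fit, dmap=dmap)


@pytest.fixture(scope="session")
def small_atlas(small_scheme):
    return h.make_fc_atlas(small_scheme, n_subjects=12, T=150,
                           community_strength=0.7, seed=41)


# --------------------------------------------------------------------------
# leakage bundle: correctly specified 4-site control cohort (site-leakage and
# calibration diagnostics)


@pytest.fixture(scope="session")
def leakage_bundle():
    scheme = h.make_parcellation(60, 6, 3, seed=51)
    cohort = h.make_cohort(scheme, [(f"site{i + 1}", 60, 0) for i in range(4)], seed=52)
    train, test = h.split_train_test(cohort, seed=53)
    fit = h.fit_normative(train, min_batch=5)
    dmap = h.deviation_map(fit, test)
    return dict(scheme=scheme, cohort=cohort, train=train, test=test,
                fit=fit, dmap=dmap)


# --------------------------------------------------------------------------
# dissociation bundle: 200-region study with a full circuit cache and the two
# deviation scenarios whose contrast the framework exists to make
# (burden-only vs circuit-convergent), 60 cases vs 60 held-out controls


def _study_cohort(scheme, scenario_kind, hubs, coupling, seed):
    cohort = h.make_cohort(scheme, [("sX", 300, 30), ("sY", 300, 30)], seed=seed)
    if scenario_kind == "null":
        return cohort
    scen = h.DeviationScenario(
        kind=scenario_kind,
        burden_distribution=h.ZeroInflatedPoisson(mean=6.0, pi=0.1),
        effect_size=4.0,
        hub_set=hubs if scenario_kind == "circuit_convergent" else (),
        seed=seed + 1)
    return h.inject_case_deviations(cohort, scheme, coupling, scen)


@pytest.fixture(scope="session")
def dissociation_bundle():
    scheme = h.make_parcellation(192, 8, 3, seed=61)
    # two hub regions from the largest cortical network
    net = scheme.regions.loc[scheme.is_cortex(), "network10"]
    big = net.value_counts().index[0]
    hubs = tuple(int(r) for r in net[net == big].index[:2])
    coupling = reference_coupling(scheme, hub_regions=hubs)
    eligible = coupling[:, scheme.regions.index.get_indexer(hubs)].mean(axis=1)
    hub_coupled = eligible > np.quantile(eligible, 0.80)

    atlas = h.make_fc_atlas(scheme, n_subjects=30, T=200, hub_regions=hubs, seed=62)
    cache = h.compute_circuit_cache(atlas, scheme, n_perm=500, alpha=0.025, seed=63)

    out = dict(scheme=scheme, atlas=atlas, cache=cache, hubs=hubs,
               hub_coupled=hub_coupled)
    for kind, seed in (("burden_only", 70), ("circuit_convergent", 80)):
        cohort = _study_cohort(scheme, kind, hubs, coupling, seed)
        train, test = h.split_train_test(cohort, seed=seed + 2)
        fit = h.fit_normative(train, min_batch=5)
        dmap = h.deviation_map(fit, test)
        groups = dmap.groups
        out[kind] = dict(
            dmap=dmap,
            case_mask=groups.str.startswith("case:").to_numpy(),
            hc_mask=(groups == "HC_test").to_numpy())
    return out
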