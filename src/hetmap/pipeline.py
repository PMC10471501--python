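"""End-to-end orchestration: cohort -> normative fit -> deviation maps ->
regional / circuit / network overlap inference -> tabular outputs + manifest.

All stage functions are importable on their own; ``run_pipeline`` chains them,
writes every declared table under ``out_dir`` and finishes with a JSON manifest
(config, seeds, declared outputs, checksums) from which every number in every
output table is reproducible.  Outputs are deterministic for a fixed config:
rerunning produces bit-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circuit as circuit_mod
from .cohort import CohortTable
from .fc_atlas import FCAtlas
from .inference import (crossscale_contrast, group_permutation_test,
                        spatial_null_test)
from .network import assign_networks, membership_matrix, network_deviance, network_overlap
from .normative import deviation_map, fit_normative, split_train_test
from .overlap import (SIGNS, delta_overlap, deviation_burden, extremes_for_sign,
                      overlap_map, threshold_weighted_overlap,
                      weighted_survival_scores)
from .parcellation import ParcellationScheme

log = logging.getLogger("hetmap")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full analysis run (defaults follow the reference
    analysis: z threshold 2.6, weighted range 1.64–3.10 in 100 log steps,
    parcel fraction 0.5, per-compartment FWE alpha 0.05/2, BH q 0.05)."""

    cohort_path: str = ""
    parcellation_path: str = ""
    atlas_dir: str = ""
    out_dir: str = "results/run"
    z_thr: float = 2.6
    z_min: float = 1.64
    z_max: float = 3.10
    n_thr: int = 100
    parcel_frac: float = 0.5
    network_level: int = 10
    alpha_fwe: float = 0.05 / 2  # cortex and subcortex tested separately
    n_perm_group: int = 10_000
    n_perm_spatial: int = 10_000
    n_perm_tfce: int = 500
    q_fdr: float = 0.05
    train_frac: float = 0.9
    site_min_for_split: int = 30
    min_batch: int = 10
    signs: tuple = ("negative", "positive")       # regional + weighted pipelines
    circuit_signs: tuple = ("negative",)          # circuit/network/cross-scale
    seed_split: int = 11
    seed_circuit: int = 23
    seed_group: int = 37
    seed_spatial: int = 53

    def validate(self) -> None:
        for name in ("z_thr", "z_min", "z_max", "parcel_frac", "alpha_fwe", "q_fdr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.z_max > self.z_min:
            raise ValueError("z_max must exceed z_min")
        if self.network_level not in (10, 20):
            raise ValueError("network_level must be 10 or 20")
        for s in tuple(self.signs) + tuple(self.circuit_signs):
            if s not in SIGNS:
                raise ValueError(f"unknown sign {s!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["signs"] = list(self.signs)
        d["circuit_signs"] = list(self.circuit_signs)
        return d

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        d["signs"] = tuple(d.get("signs", ("negative", "positive")))
        d["circuit_signs"] = tuple(d.get("circuit_signs", ("negative",)))
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def read_tables(config: RunConfig) -> tuple[CohortTable, ParcellationScheme, FCAtlas]:
    """Load and validate the three inputs; cohort regions must all exist in
    the parcellation."""
    scheme = ParcellationScheme.read(config.parcellation_path)
    cohort = CohortTable.read(config.cohort_path)
    unknown = set(cohort.region_ids) - set(scheme.region_ids)
    if unknown:
        raise ValueError(f"cohort references regions absent from the parcellation: "
                         f"{sorted(unknown)[:5]}")
    atlas = FCAtlas.read(config.atlas_dir)
    return cohort, scheme, atlas


def read_z_maps(path) -> tuple[pd.DataFrame, pd.Series]:
    """Load a deviation z-map table written by ``DeviationMap.write``;
    returns (z with integer region columns, per-subject group labels)."""
    df = pd.read_csv(path, sep="\t").set_index("subject_id")
    groups = df.pop("group")
    df.columns = df.columns.astype(int)
    return df, groups


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, cohort: CohortTable | None = None,
                 scheme: ParcellationScheme | None = None,
                 atlas: FCAtlas | None = None) -> dict:
    """Run the full analysis and write all declared outputs under ``out_dir``.

    Inputs may be passed in memory (tests, analysis drivers) or read from the
    configured paths.  Any stage failure aborts with the stage name; outputs
    written so far are left on disk and flagged incomplete in the manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = dict(config=config.to_dict(), config_hash=config.config_hash(),
                          status="incomplete", outputs=[])
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    stage = "read_tables"
    try:
        if cohort is None or scheme is None or atlas is None:
            cohort, scheme, atlas = read_tables(config)
        if len(cohort.region_ids) < scheme.n_regions:
            # tolerate regions declared in the parcellation but absent from
            # the phenotype table (e.g. parcels lost in projection)
            log.warning("cohort covers %d of %d declared regions; restricting",
                        len(cohort.region_ids), scheme.n_regions)
            scheme = scheme.subset(cohort.region_ids)
        region_ids = scheme.region_ids
        cohort_regions = cohort.phenotype.loc[:, region_ids]  # enforce scheme order
        cohort = CohortTable(cohort.subjects, cohort_regions, cohort.gen_params)

        stage = "normative_fit"
        log.info("stage %s", stage)
        train, test = split_train_test(cohort, train_frac=config.train_frac,
                                       site_min_for_split=config.site_min_for_split,
                                       min_batch=config.min_batch, seed=config.seed_split)
        fit = fit_normative(train, min_batch=min(config.min_batch, 3))
        emit("model.json", fit.to_json)
        dmap = deviation_map(fit, test, z_thr=config.z_thr)
        emit("z_maps.tsv", dmap.write)

        stage = "burden"
        burden = deviation_burden(dmap.pos_extreme, dmap.neg_extreme)
        burden.insert(0, "group", dmap.groups)
        emit("burden.tsv", lambda p: burden.to_csv(p, sep="\t", index_label="subject_id"))

        groups = dmap.groups
        case_names = sorted(g for g in groups.unique() if g.startswith("case:"))
        hc_mask = (groups == "HC_test").to_numpy()
        if not case_names or not hc_mask.any():
            raise ValueError("test set must contain HC_test and at least one case group")

        stage = "regional"
        log.info("stage %s", stage)
        for sign in config.signs:
            rows = []
            ext = extremes_for_sign(dmap.z, sign, config.z_thr)
            for gname in case_names:
                cmask = (groups == gname).to_numpy()
                omap_case = overlap_map(ext[cmask], gname, sign)
                omap_hc = overlap_map(ext[hc_mask], "HC_test", sign)
                dlt = delta_overlap(omap_case, omap_hc)
                gtest = group_permutation_test(ext.to_numpy()[cmask], ext.to_numpy()[hc_mask],
                                               n_perm=config.n_perm_group,
                                               seed=config.seed_group, q=config.q_fdr,
                                               units=ext.columns)
                stest = spatial_null_test(dmap.z, scheme, cmask, hc_mask,
                                          downstream="regional", sign=sign,
                                          z_thr=config.z_thr,
                                          n_perm=config.n_perm_spatial,
                                          seed=config.seed_spatial, q=config.q_fdr)
                rows.append(_result_table(gname, sign, omap_case.values,
                                          omap_hc.values, dlt.values, gtest, stest))
            emit(f"regional_{sign}.tsv",
                 lambda p, rows=rows: pd.concat(rows).to_csv(p, sep="\t", index=False))

        stage = "weighted"
        log.info("stage %s", stage)
        for sign in config.signs:
            rows = []
            scores = weighted_survival_scores(dmap.z, sign, config.z_min,
                                              config.z_max, config.n_thr)
            for gname in case_names:
                cmask = (groups == gname).to_numpy()
                w_case = threshold_weighted_overlap(dmap.z[cmask], sign, gname,
                                                    config.z_min, config.z_max, config.n_thr)
                w_hc = threshold_weighted_overlap(dmap.z[hc_mask], sign, "HC_test",
                                                  config.z_min, config.z_max, config.n_thr)
                gtest = group_permutation_test(scores.to_numpy()[cmask],
                                               scores.to_numpy()[hc_mask],
                                               n_perm=config.n_perm_group,
                                               seed=config.seed_group, q=config.q_fdr,
                                               units=scores.columns)
                stest = spatial_null_test(dmap.z, scheme, cmask, hc_mask,
                                          downstream="weighted", sign=sign,
                                          weighted_range=(config.z_min, config.z_max,
                                                          config.n_thr),
                                          n_perm=config.n_perm_spatial,
                                          seed=config.seed_spatial, q=config.q_fdr)
                rows.append(_result_table(gname, sign, w_case.values, w_hc.values,
                                          w_case.values - w_hc.values, gtest, stest))
            emit(f"weighted_{sign}.tsv",
                 lambda p, rows=rows: pd.concat(rows).to_csv(p, sep="\t", index=False))

        stage = "circuit_cache"
        log.info("stage %s (this is the expensive stage)", stage)
        cache = circuit_mod.compute_circuit_cache(
            atlas, scheme, n_perm=config.n_perm_tfce, alpha=config.alpha_fwe,
            frac=config.parcel_frac, seed=config.seed_circuit)
        emit("circuit_cache.tsv", cache.write)
        C = cache.as_array(region_ids)

        mapping = assign_networks(scheme, config.network_level)
        M, net_names = membership_matrix(mapping)

        for sign in config.circuit_signs:
            ext = extremes_for_sign(dmap.z, sign, config.z_thr)
            unions = circuit_mod.union_maps_for_group(ext, cache)

            stage = f"circuit_{sign}"
            log.info("stage %s", stage)
            rows = []
            for gname in case_names:
                cmask = (groups == gname).to_numpy()
                o_case = circuit_mod.circuit_overlap(unions[cmask], gname, sign)
                o_hc = circuit_mod.circuit_overlap(unions[hc_mask], "HC_test", sign)
                gtest = group_permutation_test(unions.to_numpy()[cmask],
                                               unions.to_numpy()[hc_mask],
                                               n_perm=config.n_perm_group,
                                               seed=config.seed_group, q=config.q_fdr,
                                               units=unions.columns)
                stest = spatial_null_test(dmap.z, scheme, cmask, hc_mask,
                                          downstream="circuit", sign=sign,
                                          z_thr=config.z_thr, circuit_matrix=C,
                                          n_perm=config.n_perm_spatial,
                                          seed=config.seed_spatial, q=config.q_fdr)
                rows.append(_result_table(gname, sign, o_case.values, o_hc.values,
                                          o_case.values - o_hc.values, gtest, stest))
            emit(f"circuit_{sign}.tsv",
                 lambda p, rows=rows: pd.concat(rows).to_csv(p, sep="\t", index=False))

            stage = f"network_{sign}"
            log.info("stage %s", stage)
            dev = network_deviance(ext, mapping)
            rows = []
            for gname in case_names:
                cmask = (groups == gname).to_numpy()
                o_case = network_overlap(dev[cmask], gname, sign)
                o_hc = network_overlap(dev[hc_mask], "HC_test", sign)
                gtest = group_permutation_test(dev.to_numpy()[cmask], dev.to_numpy()[hc_mask],
                                               n_perm=config.n_perm_group,
                                               seed=config.seed_group, q=config.q_fdr,
                                               units=dev.columns)
                # the spatial test reuses the rotation ensemble of the circuit test
                stest = spatial_null_test(dmap.z, scheme, cmask, hc_mask,
                                          downstream="network", sign=sign,
                                          z_thr=config.z_thr, network_membership=M,
                                          network_names=net_names,
                                          n_perm=config.n_perm_spatial,
                                          seed=config.seed_spatial, q=config.q_fdr)
                rows.append(_result_table(gname, sign, o_case.values, o_hc.values,
                                          o_case.values - o_hc.values, gtest, stest))
            emit(f"network_{sign}.tsv",
                 lambda p, rows=rows: pd.concat(rows).to_csv(p, sep="\t", index=False))

            stage = f"crossscale_{sign}"
            log.info("stage %s", stage)
            rows = []
            for gname in case_names:
                cmask = (groups == gname).to_numpy()
                res = crossscale_contrast(ext, unions, cmask, hc_mask,
                                          n_perm=config.n_perm_group,
                                          seed=config.seed_group, q=config.q_fdr)
                tbl = res.to_frame().reset_index()
                tbl.insert(0, "sign", sign)
                tbl.insert(0, "group", gname)
                rows.append(tbl)
            emit(f"crossscale_{sign}.tsv",
                 lambda p, rows=rows: pd.concat(rows).to_csv(p, sep="\t", index=False))

        stage = "manifest"
        manifest["status"] = "complete"
    except Exception as exc:  # abort with the stage name, keep partial outputs
        manifest["failed_stage"] = stage
        manifest["outputs"] = [p.name for p in written]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    manifest["outputs"] = sorted(p.name for p in written) + ["manifest.json"]
    manifest["checksums"] = {p.name: _sha256(p) for p in written}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return dict(out_dir=out, outputs=manifest["outputs"], manifest=manifest)


def _result_table(group: str, sign: str, overlap_case: pd.Series,
                  overlap_control: pd.Series, delta: pd.Series,
                  group_test, spatial_test) -> pd.DataFrame:
    """One tidy row per region combining overlap values and both null models."""
    return pd.DataFrame({
        "group": group, "sign": sign,
        "unit": np.asarray(delta.index),
        "overlap_case": np.asarray(overlap_case),
        "overlap_control": np.asarray(overlap_control),
        "delta": np.asarray(delta),
        "p_group": group_test.p_unc, "sig_group_unc": group_test.sig_unc,
        "sig_group_fdr": group_test.p_fdr_flags,
        "p_spatial": spatial_test.p_unc, "sig_spatial_unc": spatial_test.sig_unc,
        "sig_spatial_fdr": spatial_test.p_fdr_flags,
    })
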