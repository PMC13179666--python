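"""End-to-end pipeline: simulate -> harmonize -> graph metrics -> Z -> stats.

Stage order is fixed: batch harmonization first (volumes and connectivity
edges), then eTIV adjustment (volumes only), then graph metrics, then the
control-referenced age/sex GLM with hemisphere-wise Z-scoring, laterality
relabeling, and finally the group-level statistical battery.  Every stage
writes its table to the output directory and the manifest records row
counts and hashes, so a run is reproducible and auditable end to end.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as chrt
from .atlas import SUBDIVISIONS, default_atlas
from .cohort import CohortConfig, GroundTruth
from .harmonize import harmonize, harmonize_matrices, harmonization_report
from .network import strength_auc_table, validate_matrix
from .normalize import (
    StagedTable,
    adjust_for_etiv,
    fit_normative_model,
    relabel_laterality,
    zscore_to_controls,
)
from .stats import (
    anova_table,
    control_profile,
    edgewise_map,
    mixed_anova,
    one_sample_t,
    paired_t,
    pearson_corr,
)

MEASURES = ("strength_auc", "volume")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    strength_signed: bool = True
    etiv_method: str = "residual"           # 'residual' | 'ratio'
    glm_population: str = "controls"        # 'controls' | 'all'
    multivariate_stat: str = "pillai"       # 'pillai' | 'wilks'
    one_sample_family: int = 8              # 4 subdivisions x 2 lateralities
    paired_family: int = 4                  # 4 subdivisions
    correlation_family: int = 8
    write_matrices: bool = False
    out_dir: str = "thalnet_run"

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(float_format="%.12g").encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage computations (importable without touching the filesystem)


def simulate_cohort(config: CohortConfig):
    """Generate subjects, raw volumes, raw matrices (+batch effects), truth."""
    subjects, truth = chrt.generate_cohort(config)
    volumes = chrt.generate_volumes(subjects, config, truth)
    volumes = chrt.apply_batch_effects_to_volumes(
        volumes, subjects, config, truth
    )
    matrices = chrt.generate_connectivity(subjects, config, truth)
    matrices = chrt.apply_batch_effects_to_matrices(
        matrices, subjects, config, truth
    )
    return subjects, volumes, matrices, truth


def _covariate_table(subjects: pd.DataFrame) -> pd.DataFrame:
    """Numeric-coded covariates preserved during harmonization."""
    return pd.DataFrame(
        {
            "age": subjects["age"].astype(float),
            "sex_m": (subjects["sex"] == "M").astype(float),
            "patient": (subjects["group"] != "control").astype(float),
        },
        index=subjects.index,
    )


def compute_measures(
    subjects: pd.DataFrame,
    volumes: pd.DataFrame,
    matrices: dict[str, np.ndarray],
    run: RunConfig,
):
    """Harmonize, adjust, score: returns Z tables (L/R keyed) per measure
    plus intermediate stage tables and harmonization diagnostics."""
    atlas = default_atlas()
    batch = subjects["scanner_batch"]
    covs = _covariate_table(subjects)
    vol_feats = chrt.volume_feature_names()

    artifacts: dict = {}

    # --- harmonization
    single_batch = batch.nunique() < 2
    if single_batch:
        vol_harm = volumes[vol_feats].astype(float).copy()
        mats_harm = matrices
    else:
        vol_harm, vol_model = harmonize(volumes[vol_feats], batch, covs)
        artifacts["volume_combat"] = vol_model
        mats_harm, edge_model = harmonize_matrices(matrices, batch, covs)
        artifacts["edge_combat"] = edge_model
        artifacts["volume_harmonization_report"] = harmonization_report(
            volumes[vol_feats], vol_harm, batch
        )
    staged_vol = StagedTable(volumes[vol_feats], "raw").advance(
        vol_harm, "harmonized"
    )

    # --- eTIV adjustment (volumes only)
    controls = subjects["group"] == "control"
    vol_adj = adjust_for_etiv(
        staged_vol.table, volumes["etiv"], controls, method=run.etiv_method
    )
    staged_vol = staged_vol.advance(vol_adj, "etiv_adjusted")

    # --- graph metrics on harmonized matrices
    auc_all = strength_auc_table(
        mats_harm, atlas.labels, signed=run.strength_signed
    )
    thal_cols = [
        f"{h}_thal_{s}" for h in ("L", "R") for s in SUBDIVISIONS
    ]
    auc = auc_all[thal_cols].rename(
        columns=lambda c: c.replace("thal_", "")
    )  # -> '<L|R>_<subdivision>'

    # --- normative GLM + hemisphere-wise Z
    z_tables = {}
    models = {}
    for measure, table in (("volume", staged_vol.table), ("strength_auc", auc)):
        ref = table if run.glm_population == "all" else table.loc[controls]
        model = fit_normative_model(
            ref, subjects["age"], subjects["sex"]
        )
        z = zscore_to_controls(table, model, subjects["age"], subjects["sex"])
        z_tables[measure] = z
        models[measure] = model
    artifacts["normative_models"] = models
    artifacts["matrices_harmonized"] = mats_harm
    artifacts["volume_stages"] = staged_vol
    artifacts["auc"] = auc
    return z_tables, artifacts


def relabel_patients(
    z_tables: dict[str, pd.DataFrame], subjects: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Ipsi/contra-keyed Z tables for patients only."""
    patients = subjects.index[subjects["focus_side"].isin(["L", "R"])]
    return {
        m: relabel_laterality(z.loc[patients], subjects["focus_side"])
        for m, z in z_tables.items()
    }


# ---------------------------------------------------------------------------
# the statistical battery


def _long_format_lr(z: pd.DataFrame, subjects: pd.DataFrame, measure: str):
    long = z.reset_index().melt(
        id_vars="subject_id", var_name="feature", value_name="value"
    )
    long["nucleus"] = long["feature"]  # 8 hemisphere-specific levels
    long["measure"] = measure
    long = long.merge(
        subjects[["group"]].reset_index(), on="subject_id"
    )
    return long


def _long_format_ipsicontra(zp: pd.DataFrame, subjects: pd.DataFrame):
    long = zp.reset_index().melt(
        id_vars="subject_id", var_name="feature", value_name="value"
    )
    long[["laterality", "nucleus"]] = long["feature"].str.split(
        "_", n=1, expand=True
    )
    return long.merge(subjects.reset_index(), on="subject_id")


def group_anovas(
    z_tables, z_patients, subjects, run: RunConfig
) -> pd.DataFrame:
    """The two primary mixed ANOVAs per measure (Table-2-like block)."""
    frames = []
    for measure in MEASURES:
        # controls + all patients, 8 hemisphere-specific nuclei
        long = _long_format_lr(z_tables[measure], subjects, measure)
        long["cohort"] = np.where(long["group"] == "control",
                                  "control", "epilepsy")
        res = mixed_anova(long, "value", "subject_id", ["nucleus"], "cohort")
        t = anova_table(res)
        t.insert(0, "analysis", "overall_vs_controls")
        t.insert(0, "measure", measure)
        frames.append(t)
        # patients only: 3 groups x nuclei x laterality
        longp = _long_format_ipsicontra(z_patients[measure], subjects)
        res = mixed_anova(
            longp, "value", "subject_id", ["nucleus", "laterality"], "group"
        )
        t = anova_table(res)
        t.insert(0, "analysis", "TLE_FLE_PQE")
        t.insert(0, "measure", measure)
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    return out


SUBGROUPINGS = {
    "HS_vs_NoHS": ("hs_status", ["HS", "NoHS"], "TLE"),
    "FBTCS": ("fbtcs", ["yes", "no"], None),
    "status_epilepticus": ("status_epilepticus", ["yes", "no"], None),
    "etiology": ("etiology", ["acquired", "congenital"], None),
    "seizure_free": ("seizure_free", ["yes", "no"], None),
}


def subgroup_contrast(
    z_patients: dict[str, pd.DataFrame],
    subjects: pd.DataFrame,
    grouping: str,
    measure: str = "volume",
) -> pd.DataFrame:
    """Three-way mixed ANOVA for a clinical dichotomy.

    Subjects with unknown/absent labels for the dichotomy are excluded
    per-analysis, never globally.
    """
    if grouping not in SUBGROUPINGS:
        raise KeyError(
            f"unknown grouping {grouping!r}; options: {sorted(SUBGROUPINGS)}"
        )
    column, levels, restrict_group = SUBGROUPINGS[grouping]
    sel = subjects[column].isin(levels)
    if restrict_group:
        sel &= subjects["group"] == restrict_group
    kept = subjects[sel]
    for lev in levels:
        if (kept[column] == lev).sum() < 2:
            raise ValueError(
                f"subgroup level {lev!r} has <2 subjects after filtering"
            )
    zp = z_patients[measure].loc[z_patients[measure].index.intersection(kept.index)]
    long = _long_format_ipsicontra(zp, kept)
    res = mixed_anova(
        long, "value", "subject_id", ["nucleus", "laterality"], column
    )
    t = anova_table(res)
    t.insert(0, "analysis", grouping)
    t.insert(0, "measure", measure)
    t.insert(0, "n", len(zp))
    return t


def planned_tests(
    z_patients: dict[str, pd.DataFrame],
    subjects: pd.DataFrame,
    run: RunConfig,
) -> pd.DataFrame:
    """Table-3-like battery: one-sample and paired t-tests with Cohen d.

    One-sample tests compare each patient group's Z-scores to zero (the
    control mean); paired tests compare ipsi vs contra within group.
    """
    rows = []
    group_sets = [("overall", None)] + [(g, g) for g in chrt.PATIENT_GROUPS]
    for measure in MEASURES:
        zp = z_patients[measure]
        for gname, gsel in group_sets:
            if gsel is None:
                idx = zp.index
            else:
                idx = zp.index.intersection(
                    subjects.index[subjects["group"] == gsel]
                )
            if len(idx) < 3:
                continue
            for sub in SUBDIVISIONS:
                for lat in ("ipsi", "contra"):
                    res = one_sample_t(
                        zp.loc[idx, f"{lat}_{sub}"].to_numpy(),
                        m=run.one_sample_family,
                    )
                    rows.append(dict(
                        measure=measure, group=gname, nucleus=sub,
                        laterality=lat, test="one_sample", n=res.n,
                        mean=res.mean, sd=res.sd, t=res.t,
                        p_uncorrected=res.p_uncorrected,
                        p_corrected=res.p_bonferroni, cohen_d=res.cohen_d,
                        mean_diff=np.nan,
                    ))
                res = paired_t(
                    zp.loc[idx, f"ipsi_{sub}"].to_numpy(),
                    zp.loc[idx, f"contra_{sub}"].to_numpy(),
                    m=run.paired_family,
                )
                rows.append(dict(
                    measure=measure, group=gname, nucleus=sub,
                    laterality="ipsi_vs_contra", test="paired", n=res.n,
                    mean=res.mean, sd=res.sd, t=res.t,
                    p_uncorrected=res.p_uncorrected,
                    p_corrected=res.p_bonferroni, cohen_d=res.cohen_d,
                    mean_diff=res.mean_diff,
                ))
    return pd.DataFrame(rows)


def correlation_battery(
    z_patients: dict[str, pd.DataFrame],
    subjects: pd.DataFrame,
    run: RunConfig,
) -> pd.DataFrame:
    """Volume vs strength AUC, and each vs epilepsy duration, per feature."""
    rows = []
    zv, zs = z_patients["volume"], z_patients["strength_auc"]
    dur = subjects["duration_years"].reindex(zv.index)
    for sub in SUBDIVISIONS:
        for lat in ("ipsi", "contra"):
            feat = f"{lat}_{sub}"
            res = pearson_corr(
                zv[feat].to_numpy(), zs[feat].to_numpy(),
                m=run.correlation_family,
            )
            rows.append(dict(
                pair="volume_vs_strength", nucleus=sub, laterality=lat,
                r=res.r, n=res.n, p_uncorrected=res.p_uncorrected,
                p_corrected=res.p_corrected,
            ))
            ok = dur.notna()
            for name, z in (("duration_vs_volume", zv), ("duration_vs_strength", zs)):
                res = pearson_corr(
                    dur[ok].to_numpy(), z.loc[ok, feat].to_numpy(),
                    m=run.correlation_family,
                )
                rows.append(dict(
                    pair=name, nucleus=sub, laterality=lat,
                    r=res.r, n=res.n, p_uncorrected=res.p_uncorrected,
                    p_corrected=res.p_corrected,
                ))
    return pd.DataFrame(rows)


def edgewise_battery(
    matrices: dict[str, np.ndarray],
    subjects: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Control edge profiles (top 10) and patients-vs-controls t-maps."""
    atlas = default_atlas()
    ctrl_ids = subjects.index[subjects["group"] == "control"]
    ctrl_mats = {s: matrices[s] for s in ctrl_ids}
    covs = pd.DataFrame(
        {"age": subjects["age"], "sex_m": (subjects["sex"] == "M").astype(float)}
    )
    profiles = pd.concat(
        [control_profile(ctrl_mats, atlas, s, covariates=covs, top_k=10)
         for s in SUBDIVISIONS],
        ignore_index=True,
    )
    maps = []
    for group in chrt.PATIENT_GROUPS:
        gids = subjects.index[subjects["group"] == group]
        if len(gids) < 2:
            continue
        gmats = {s: matrices[s] for s in gids}
        for sub in SUBDIVISIONS:
            for side in ("L", "R"):
                t = edgewise_map(gmats, ctrl_mats, atlas, sub, side)
                t.insert(0, "group", group)
                maps.append(t)
    return profiles, pd.concat(maps, ignore_index=True)


# ---------------------------------------------------------------------------
# validation & orchestration


def validate_inputs(
    subjects: pd.DataFrame,
    volumes: pd.DataFrame | None = None,
    matrices: dict[str, np.ndarray] | None = None,
) -> list[dict]:
    """Machine-readable problem list; reports, never raises."""
    problems = []
    atlas = default_atlas()
    required = {"group", "age", "sex", "focus_side", "scanner_batch", "etiv"}
    missing_cols = required - set(subjects.columns)
    if missing_cols:
        problems.append({"kind": "metadata_columns_missing",
                         "detail": sorted(missing_cols)})
        return problems
    pat = subjects["group"] != "control"
    bad_side = pat & ~subjects["focus_side"].isin(["L", "R"])
    for sid in subjects.index[bad_side]:
        problems.append({"kind": "missing_focus_side", "subject": sid})
    for sid in subjects.index[subjects["etiv"] <= 0]:
        problems.append({"kind": "non_positive_etiv", "subject": sid})
    if volumes is not None:
        vol_cols = [c for c in volumes.columns if c != "etiv"]
        neg = (volumes[vol_cols] <= 0).any(axis=1)
        for sid in volumes.index[neg]:
            problems.append({"kind": "non_positive_volume", "subject": sid})
    if matrices is not None:
        for sid, m in matrices.items():
            if m.shape != (len(atlas), len(atlas)):
                problems.append({"kind": "matrix_shape", "subject": sid,
                                 "shape": list(m.shape)})
                continue
            asym = float(np.abs(m - m.T).max())
            if asym > 1e-8:
                problems.append({"kind": "asymmetric_matrix", "subject": sid,
                                 "max_abs_asymmetry": asym})
            if not np.isfinite(m).all():
                problems.append({"kind": "non_finite_matrix", "subject": sid})
    return problems


def run_pipeline(run: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts to ``out_dir``."""
    t0 = time.time()
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": run.config_hash(),
        "config": _jsonable(asdict(run)),
        "stages": {},
    }

    def log(stage, df):
        manifest["stages"][stage] = {
            "rows": int(len(df)), "hash": _hash_df(df)
        }

    try:
        subjects, volumes, matrices, truth = simulate_cohort(run.cohort)
        problems = validate_inputs(subjects, volumes, matrices)
        if problems:
            raise RuntimeError(f"stage simulate: invalid inputs: {problems[:3]}")
        subjects.to_csv(out / "subjects.tsv", sep="\t")
        volumes.to_csv(out / "volumes_raw.tsv", sep="\t")
        truth.to_json(out / "ground_truth.json")
        log("simulate", subjects)
        if run.write_matrices:
            mdir = out / "matrices"
            mdir.mkdir(exist_ok=True)
            atlas = default_atlas()
            for sid, m in matrices.items():
                pd.DataFrame(m, index=atlas.labels, columns=atlas.labels).to_csv(
                    mdir / f"{sid}.csv"
                )

        z_tables, artifacts = compute_measures(subjects, volumes, matrices, run)
        artifacts["volume_stages"].table.to_csv(
            out / "volumes_adjusted.tsv", sep="\t"
        )
        artifacts["auc"].to_csv(out / "strength_auc.tsv", sep="\t")
        for m, z in z_tables.items():
            z.to_csv(out / f"z_{m}_lr.tsv", sep="\t")
            log(f"z_{m}", z)

        z_patients = relabel_patients(z_tables, subjects)
        for m, z in z_patients.items():
            z.to_csv(out / f"z_{m}_ipsicontra.tsv", sep="\t")

        anovas = group_anovas(z_tables, z_patients, subjects, run)
        sub_frames = []
        for grouping in SUBGROUPINGS:
            for measure in MEASURES:
                try:
                    sub_frames.append(
                        subgroup_contrast(z_patients, subjects, grouping, measure)
                    )
                except ValueError:
                    continue  # level empty in a small cohort
        table2 = pd.concat(
            [anovas.assign(n=np.nan)] + sub_frames, ignore_index=True
        )
        table2.to_csv(out / "table2_like.tsv", sep="\t", index=False)
        log("anovas", table2)

        table3 = planned_tests(z_patients, subjects, run)
        table3.to_csv(out / "table3_like.tsv", sep="\t", index=False)
        log("planned_tests", table3)

        corrs = correlation_battery(z_patients, subjects, run)
        corrs.to_csv(out / "correlations.tsv", sep="\t", index=False)
        log("correlations", corrs)

        profiles, maps = edgewise_battery(
            artifacts["matrices_harmonized"], subjects
        )
        profiles.to_csv(out / "control_profiles_top10.tsv", sep="\t", index=False)
        maps.to_csv(out / "edgewise_tmaps.tsv", sep="\t", index=False)
        log("edgewise", maps)
    except Exception as err:
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    manifest["wall_seconds"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
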