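"""Synthetic cohort generator.

Emulates the statistical structure of a pediatric focal-epilepsy imaging
cohort: demographics and clinical labels for four groups (controls, TLE,
FLE, PQE), THOMAS-style thalamic subdivision volumes, CONN-style 122x122
Pearson connectivity matrices, scanner-batch effects, and planted
group-level effects expressed as Cohen d on the downstream Z-scored
measures.  The defaults reproduce the published cohort composition
(81 TLE / 36 FLE / 19 PQE / 70 controls) and headline effect sizes.

No fMRI time series or scanner physics are simulated; generation starts at
the matrix/volume level.  The population mean connectivity matrix is
synthetic: a block structure qualitatively echoing known thalamic
connectivity profiles, not an empirical group average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, SUBDIVISIONS, default_atlas
from .network import strength_auc_matrix

GROUPS = ("control", "TLE", "FLE", "PQE")
PATIENT_GROUPS = ("TLE", "FLE", "PQE")

#: clinical fractions per patient group: (yes, no, unknown) must sum to 1
_T1 = {
    "TLE": dict(n=81, age=(13.1, 3.0), female=46 / 81, left=62 / 81,
                duration=(6.5, 4.1), hs=28 / 81,
                fbtcs=(29 / 81, 46 / 81, 6 / 81),
                status_epilepticus=(21 / 81, 60 / 81, 0.0),
                etiology=(63 / 81, 11 / 81, 7 / 81),
                seizure_free=(40 / 81, 13 / 81, 28 / 81)),
    "FLE": dict(n=36, age=(11.8, 3.2), female=19 / 36, left=27 / 36,
                duration=(5.8, 3.8), hs=0.0,
                fbtcs=(8 / 36, 27 / 36, 1 / 36),
                status_epilepticus=(8 / 36, 27 / 36, 1 / 36),
                etiology=(12 / 36, 15 / 36, 9 / 36),
                seizure_free=(14 / 36, 11 / 36, 11 / 36)),
    "PQE": dict(n=19, age=(13.2, 3.1), female=11 / 19, left=13 / 19,
                duration=(7.6, 4.0), hs=0.0,
                fbtcs=(8 / 19, 11 / 19, 0.0),
                status_epilepticus=(4 / 19, 15 / 19, 0.0),
                etiology=(14 / 19, 3 / 19, 2 / 19),
                seizure_free=(4 / 19, 4 / 19, 11 / 19)),
    "control": dict(n=70, age=(13.4, 3.1), female=34 / 70),
}


@dataclass
class PlantedEffect:
    """A group-level effect in standardized (Cohen d) units.

    ``group`` selects the affected subjects: 'patients', one of
    'TLE'/'FLE'/'PQE', 'TLE_HS', 'TLE_NoHS', or 'acquired'/'congenital'.
    ``laterality``: 'ipsi', 'contra', or 'both' — mapped through each
    subject's focus side.
    """

    measure: str  # 'strength_auc' or 'volume'
    subdivision: str
    laterality: str
    group: str
    cohen_d: float


@dataclass
class DurationEffect:
    """Planted correlation between epilepsy duration and a feature."""

    measure: str
    subdivision: str
    laterality: str
    group: str
    r: float


@dataclass
class BatchEffect:
    """Scanner-batch perturbation injected into the designated batch.

    Volume offsets are expressed in units of the per-feature noise SD;
    edge offsets directly in correlation units.
    """

    target_batch: str = "batch_3T"
    volume_offset_sd: float = 0.5
    volume_scale: float = 1.2
    edge_offset: float = 0.05
    edge_scale: float = 1.2


def default_planted_effects() -> list[PlantedEffect]:
    """Defaults mirroring the published overall-cohort effect pattern."""
    return [
        # node-strength AUC
        PlantedEffect("strength_auc", "pulvinar", "ipsi", "patients", -0.55),
        PlantedEffect("strength_auc", "pulvinar", "contra", "patients", -0.25),
        PlantedEffect("strength_auc", "anterior", "both", "TLE_NoHS", -0.40),
        # volumes
        PlantedEffect("volume", "anterior", "ipsi", "patients", -0.52),
        PlantedEffect("volume", "lateral", "ipsi", "patients", -0.50),
        PlantedEffect("volume", "lateral", "contra", "patients", -0.12),
        PlantedEffect("volume", "medial", "ipsi", "patients", 0.31),
        PlantedEffect("volume", "medial", "contra", "patients", 0.51),
        PlantedEffect("volume", "pulvinar", "ipsi", "patients", -0.09),
        PlantedEffect("volume", "pulvinar", "contra", "patients", 0.24),
    ]


def default_duration_effects() -> list[DurationEffect]:
    return [DurationEffect("volume", "lateral", "ipsi", "acquired", -0.29)]


@dataclass
class CohortConfig:
    group_sizes: dict = field(
        default_factory=lambda: {"control": 70, "TLE": 81, "FLE": 36, "PQE": 19}
    )
    age_mean: dict = field(
        default_factory=lambda: {g: _T1[g]["age"][0] for g in GROUPS}
    )
    age_sd: dict = field(
        default_factory=lambda: {g: _T1[g]["age"][1] for g in GROUPS}
    )
    age_range: tuple = (4.0, 18.0)
    female_fraction: dict = field(
        default_factory=lambda: {g: _T1[g]["female"] for g in GROUPS}
    )
    focus_left_fraction: dict = field(
        default_factory=lambda: {g: _T1[g]["left"] for g in PATIENT_GROUPS}
    )
    batch_3t_fraction: dict = field(
        default_factory=lambda: {"control": 0.0, "TLE": 33 / 136,
                                 "FLE": 33 / 136, "PQE": 33 / 136}
    )
    etiv_mean: float = 1.4e6  # mm^3
    etiv_sd: float = 1.2e5
    # THOMAS-style control mean volumes per subdivision, mm^3 per hemisphere
    volume_means: dict = field(
        default_factory=lambda: {"anterior": 140.0, "lateral": 2400.0,
                                 "medial": 1100.0, "pulvinar": 1700.0}
    )
    volume_noise_cv: float = 0.08
    # fraction of volume noise variance shared across all 8 nuclei within a
    # subject (global thalamic size factor beyond eTIV); nuclei volumes
    # co-vary strongly in real anatomy
    volume_shared_variance_frac: float = 0.45
    volume_age_slope_frac: float = 0.01   # per year, fraction of the mean
    volume_sex_offset_frac: float = 0.02  # males larger
    volume_left_asymmetry: float = 1.02
    edge_noise_sd: float = 0.10           # Fisher-z units
    planted_effects: list = field(default_factory=default_planted_effects)
    duration_effects: list = field(default_factory=default_duration_effects)
    batch_effect: BatchEffect = field(default_factory=BatchEffect)
    max_abs_cohen_d: float = 2.0
    calibration_samples: int = 60
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group size for {g} must be >= 0")
        for name, frac in [("focus_left_fraction", self.focus_left_fraction),
                           ("female_fraction", self.female_fraction),
                           ("batch_3t_fraction", self.batch_3t_fraction)]:
            for g, f in frac.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"{name}[{g}]={f} outside [0, 1]")
        for eff in self.planted_effects:
            if abs(eff.cohen_d) > self.max_abs_cohen_d:
                raise ValueError(
                    f"|cohen_d|={abs(eff.cohen_d)} exceeds the configured "
                    f"maximum {self.max_abs_cohen_d}"
                )
        if self.batch_effect.volume_scale <= 0 or self.batch_effect.edge_scale <= 0:
            raise ValueError("multiplicative batch scales must be > 0")


@dataclass
class GroundTruth:
    """What was actually planted; regeneration with the same seed is exact."""

    seed: int
    planted_effects: list
    duration_effects: list
    batch_effect: dict
    volume_feature_means: dict      # feature -> control mean (no eTIV term)
    volume_noise_sd: dict           # feature -> noise SD (mm^3)
    volume_shifts: dict             # (group_selector, feature) -> mm^3 shift
    edge_shift_z: dict              # (group_selector, node_label) -> z shift
    auc_control_sd: dict            # node_label -> calibration SD of AUC
    auc_sensitivity: dict           # node_label -> dAUC per unit z shift
    batch_offsets: dict = field(default_factory=dict)  # filled at injection

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["planted_effects"] = [asdict(e) for e in self.planted_effects]
        payload["duration_effects"] = [asdict(e) for e in self.duration_effects]

        def _keys_to_str(d):
            return {"|".join(k) if isinstance(k, tuple) else k: v
                    for k, v in d.items()}

        for key in ("volume_shifts", "edge_shift_z", "batch_offsets"):
            payload[key] = _keys_to_str(payload[key])
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, size=todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _categorical(rng, fracs, labels, size):
    p = np.asarray(fracs, dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=size, p=p)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the subject metadata table and the ground-truth record."""
    config.validate()
    rng = _rng(config, 1)
    rows = []
    counter = 0
    for group in GROUPS:
        n = int(config.group_sizes.get(group, 0))
        if n == 0:
            continue
        ages = _truncated_normal(
            rng, config.age_mean[group], config.age_sd[group],
            config.age_range[0], config.age_range[1], n,
        )
        sexes = np.where(
            rng.random(n) < config.female_fraction[group], "F", "M"
        )
        etiv = _truncated_normal(
            rng, config.etiv_mean, config.etiv_sd,
            0.5 * config.etiv_mean, 1.5 * config.etiv_mean, n,
        )
        if group == "control":
            for k in range(n):
                counter += 1
                rows.append(dict(
                    subject_id=f"sub-{counter:04d}", group=group,
                    age=ages[k], sex=sexes[k], focus_side="none",
                    scanner_batch="batch_1p5T", hs_status="NA",
                    fbtcs="NA", status_epilepticus="NA", etiology="NA",
                    seizure_free="NA", duration_years=np.nan, etiv=etiv[k],
                ))
            continue
        profile = _T1[group]
        sides = np.where(
            rng.random(n) < config.focus_left_fraction[group], "L", "R"
        )
        batches = np.where(
            rng.random(n) < config.batch_3t_fraction[group],
            "batch_3T", "batch_1p5T",
        )
        hs = (
            np.where(rng.random(n) < profile["hs"], "HS", "NoHS")
            if group == "TLE" else np.full(n, "NA")
        )
        fbtcs = _categorical(rng, profile["fbtcs"], ["yes", "no", "unknown"], n)
        se = _categorical(
            rng, profile["status_epilepticus"], ["yes", "no", "unknown"], n
        )
        etio = _categorical(
            rng, profile["etiology"], ["acquired", "congenital", "other"], n
        )
        if group == "TLE":
            # HS is by definition an acquired etiology
            etio = np.where(hs == "HS", "acquired", etio)
        sf = _categorical(
            rng, profile["seizure_free"], ["yes", "no", "unknown"], n
        )
        dur = _truncated_normal(
            rng, profile["duration"][0], profile["duration"][1], 0.5, 17.0, n
        )
        dur = np.minimum(dur, ages - 1.0)
        for k in range(n):
            counter += 1
            rows.append(dict(
                subject_id=f"sub-{counter:04d}", group=group,
                age=ages[k], sex=sexes[k], focus_side=sides[k],
                scanner_batch=batches[k], hs_status=hs[k],
                fbtcs=fbtcs[k], status_epilepticus=se[k], etiology=etio[k],
                seizure_free=sf[k], duration_years=dur[k], etiv=etiv[k],
            ))
    subjects = pd.DataFrame(rows).set_index("subject_id")

    atlas = default_atlas()
    truth = _build_ground_truth(config, atlas)
    return subjects, truth


def _selector_mask(subjects: pd.DataFrame, selector: str) -> pd.Series:
    if selector in ("patients", "all_patients"):
        return subjects["group"] != "control"
    if selector in PATIENT_GROUPS:
        return subjects["group"] == selector
    if selector == "TLE_HS":
        return (subjects["group"] == "TLE") & (subjects["hs_status"] == "HS")
    if selector == "TLE_NoHS":
        return (subjects["group"] == "TLE") & (subjects["hs_status"] == "NoHS")
    if selector in ("acquired", "congenital", "other"):
        return subjects["etiology"] == selector
    raise ValueError(f"unknown group selector {selector!r}")


def volume_feature_names() -> list[str]:
    return [f"{h}_{s}" for s in SUBDIVISIONS for h in ("L", "R")]


def _volume_feature_params(config: CohortConfig):
    means, sds = {}, {}
    for sub in SUBDIVISIONS:
        for hemi in ("L", "R"):
            asym = config.volume_left_asymmetry if hemi == "L" else 1.0
            mu = config.volume_means[sub] * asym
            means[f"{hemi}_{sub}"] = mu
            sds[f"{hemi}_{sub}"] = config.volume_noise_cv * mu
    return means, sds


def _build_ground_truth(config: CohortConfig, atlas: RegionAtlas) -> GroundTruth:
    means, sds = _volume_feature_params(config)
    volume_shifts = {}
    for eff in config.planted_effects:
        if eff.measure != "volume":
            continue
        for lat in (("ipsi", "contra") if eff.laterality == "both"
                    else (eff.laterality,)):
            # hemisphere resolved per subject at generation time; record the
            # shift magnitude per base feature (hemisphere-mean noise SD)
            sd_ref = (sds[f"L_{eff.subdivision}"] + sds[f"R_{eff.subdivision}"]) / 2
            key = (eff.group, f"{lat}_{eff.subdivision}")
            volume_shifts[key] = volume_shifts.get(key, 0.0) + eff.cohen_d * sd_ref

    mean_z = mean_connectivity_z(atlas)
    strength_effects = [
        e for e in config.planted_effects if e.measure == "strength_auc"
    ]
    edge_shift_z = {}
    if strength_effects:
        cal = _AucCalibration(config, atlas, mean_z)
        sd_auc, sens = dict(cal.sd), {}
        for eff in strength_effects:
            for lat in (("ipsi", "contra") if eff.laterality == "both"
                        else (eff.laterality,)):
                for hemi in ("L", "R"):
                    node = atlas.thalamic_label(eff.subdivision, hemi)
                    delta = cal.solve_shift(node, eff.cohen_d)
                    sens[node] = eff.cohen_d * sd_auc[node] / delta
                    key = (eff.group, lat, node)
                    edge_shift_z[key] = edge_shift_z.get(key, 0.0) + delta
    else:
        sd_auc, sens = {}, {}

    return GroundTruth(
        seed=config.seed,
        planted_effects=list(config.planted_effects),
        duration_effects=list(config.duration_effects),
        batch_effect=asdict(config.batch_effect),
        volume_feature_means=means,
        volume_noise_sd=sds,
        volume_shifts=volume_shifts,
        edge_shift_z=edge_shift_z,
        auc_control_sd=sd_auc,
        auc_sensitivity=sens,
    )


def generate_volumes(
    subjects: pd.DataFrame, config: CohortConfig, truth: GroundTruth
) -> pd.DataFrame:
    """Per-subject thalamic subdivision volumes (mm^3), 8 features + eTIV.

    Volumes are eTIV-proportional with a linear age slope, a sex offset,
    planted group shifts (mapped through each subject's focus side), planted
    duration associations, and Gaussian noise.
    """
    rng = _rng(config, 2)
    means, sds = _volume_feature_params(config)
    feats = volume_feature_names()
    ref_age = 13.0
    out = pd.DataFrame(index=subjects.index, columns=feats, dtype=float)
    rho = config.volume_shared_variance_frac
    if not 0.0 <= rho < 1.0:
        raise ValueError("volume_shared_variance_frac must be in [0, 1)")
    shared = rng.normal(size=(len(subjects), 1))
    unique = rng.normal(size=(len(subjects), len(feats)))
    noise = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * unique

    # per-selector duration slopes in raw units
    dur_slopes = {}
    for de in config.duration_effects:
        mask = _selector_mask(subjects, de.group)
        durs = subjects.loc[mask, "duration_years"].dropna()
        sigma_d = durs.std(ddof=1) if len(durs) > 2 else 1.0
        for lat in (("ipsi", "contra") if de.laterality == "both"
                    else (de.laterality,)):
            key = (de.group, f"{lat}_{de.subdivision}")
            sd_ref = (sds[f"L_{de.subdivision}"] + sds[f"R_{de.subdivision}"]) / 2
            beta_z = de.r / (sigma_d * np.sqrt(1 - de.r**2))
            dur_slopes[key] = (beta_z * sd_ref, float(durs.mean()))

    for col_idx, feat in enumerate(feats):
        hemi, sub = feat.split("_", 1)
        base = (
            means[feat]
            * (subjects["etiv"] / config.etiv_mean)
            * (1.0 + config.volume_age_slope_frac * (subjects["age"] - ref_age))
            * (1.0 + np.where(subjects["sex"] == "M",
                              config.volume_sex_offset_frac, 0.0))
        )
        vals = base + sds[feat] * noise[:, col_idx]
        # planted group shifts
        for (selector, lat_feat), shift in truth.volume_shifts.items():
            lat, s_sub = lat_feat.split("_", 1)
            if s_sub != sub:
                continue
            mask = _selector_mask(subjects, selector) & (
                subjects["focus_side"] != "none"
            )
            ipsi_is_this_hemi = subjects["focus_side"] == hemi
            affected = mask & (
                ipsi_is_this_hemi if lat == "ipsi" else ~ipsi_is_this_hemi
            )
            vals = vals + np.where(affected, shift, 0.0)
        # planted duration associations
        for (selector, lat_feat), (slope, dmean) in dur_slopes.items():
            lat, s_sub = lat_feat.split("_", 1)
            if s_sub != sub:
                continue
            mask = _selector_mask(subjects, selector) & (
                subjects["focus_side"] != "none"
            )
            ipsi_is_this_hemi = subjects["focus_side"] == hemi
            affected = mask & (
                ipsi_is_this_hemi if lat == "ipsi" else ~ipsi_is_this_hemi
            )
            centered = (subjects["duration_years"] - dmean).fillna(0.0)
            vals = vals + np.where(affected, slope * centered, 0.0)
        if (vals <= 0).any():
            bad = out.index[np.asarray(vals <= 0)][0]
            raise ValueError(
                f"non-positive volume for subject {bad}, feature {feat}; "
                "planted effect too large for the configured means/noise"
            )
        out[feat] = np.asarray(vals)
    out["etiv"] = subjects["etiv"]
    return out


# ---------------------------------------------------------------------------
# connectivity


def mean_connectivity_z(atlas: RegionAtlas) -> np.ndarray:
    """Synthetic population-mean connectivity in Fisher-z units.

    Block structure echoing qualitative thalamic connectivity profiles:
    each subdivision has a set of preferred cortical/subcortical partners;
    homotopic pairs are strong; within-hemisphere baseline exceeds
    cross-hemisphere baseline.  A small seeded jitter breaks ties.  This is
    a synthetic stand-in, not an empirical group-average matrix.
    """
    partners = {
        "anterior": ["amygdala", "hippocampus", "superior_temporal_gyrus_anterior",
                     "superior_temporal_gyrus_posterior", "superior_frontal_gyrus",
                     "middle_frontal_gyrus", "frontal_pole", "paracingulate_gyrus",
                     "caudate", "putamen", "accumbens", "paracentral_lobule",
                     "medial_orbitofrontal_cortex"],
        "lateral": ["insular_cortex", "lingual_gyrus",
                    "temporal_fusiform_cortex_anterior",
                    "temporal_fusiform_cortex_posterior",
                    "occipital_fusiform_gyrus", "paracentral_lobule",
                    "precentral_gyrus", "postcentral_gyrus",
                    "inferior_frontal_gyrus_pars_triangularis",
                    "inferior_frontal_gyrus_pars_opercularis",
                    "inferior_frontal_gyrus_pars_orbitalis",
                    "middle_temporal_gyrus_posterior", "central_opercular_cortex"],
        "medial": ["insular_cortex", "lingual_gyrus",
                   "temporal_occipital_fusiform_cortex", "paracentral_lobule",
                   "amygdala", "accumbens", "superior_temporal_gyrus_posterior",
                   "heschls_gyrus"],
        "pulvinar": ["hippocampus", "amygdala", "parahippocampal_gyrus_anterior",
                     "parahippocampal_gyrus_posterior", "entorhinal_cortex",
                     "temporal_pole", "accumbens", "insular_cortex",
                     "precuneous_cortex", "cingulate_gyrus_posterior",
                     "occipital_pole", "lateral_occipital_cortex_superior",
                     "lateral_occipital_cortex_inferior", "lingual_gyrus",
                     "cuneal_cortex"],
    }
    n = len(atlas)
    z = np.full((n, n), 0.08)
    hemi = np.array([atlas.hemisphere(lab) for lab in atlas.labels])
    same_hemi = hemi[:, None] == hemi[None, :]
    z[same_hemi] += 0.04
    # homotopic pairs
    for lab in atlas.labels:
        if lab.startswith("L_"):
            i, j = atlas.index(lab), atlas.index(atlas.homologue(lab))
            z[i, j] = z[j, i] = 0.35
    # thalamo-thalamic
    for h in ("L", "R"):
        idx = [atlas.thalamic_index(s, h) for s in SUBDIVISIONS]
        for a in range(4):
            for b in range(a + 1, 4):
                z[idx[a], idx[b]] = z[idx[b], idx[a]] = 0.50
    for s in SUBDIVISIONS:
        i, j = atlas.thalamic_index(s, "L"), atlas.thalamic_index(s, "R")
        z[i, j] = z[j, i] = 0.40
    # subdivision-specific cortical partners
    for s, plist in partners.items():
        for h in ("L", "R"):
            ti = atlas.thalamic_index(s, h)
            for p in plist:
                pi = atlas.index(f"{h}_{p}")
                z[ti, pi] = z[pi, ti] = 0.45
                pj = atlas.index(f"{'R' if h == 'L' else 'L'}_{p}")
                z[ti, pj] = z[pj, ti] = 0.25
    # designated strongest partners (stable rank-1 edges)
    for h in ("L", "R"):
        z[atlas.thalamic_index("anterior", h), atlas.index(f"{h}_amygdala")] = 0.60
        z[atlas.index(f"{h}_amygdala"), atlas.thalamic_index("anterior", h)] = 0.60
        z[atlas.thalamic_index("pulvinar", h), atlas.index(f"{h}_hippocampus")] = 0.55
        z[atlas.index(f"{h}_hippocampus"), atlas.thalamic_index("pulvinar", h)] = 0.55
    # seeded jitter: breaks the massive ties of the block construction
    jit_rng = np.random.default_rng(12345)
    jit = jit_rng.uniform(-0.02, 0.02, size=(n, n))
    z = z + np.triu(jit, 1) + np.triu(jit, 1).T
    np.fill_diagonal(z, 0.0)
    return z


def _symmetric_noise(rng, n, sd):
    a = rng.normal(0.0, sd, size=(n, n))
    a = np.triu(a, 1)
    return a + a.T


class _AucCalibration:
    """Monte-Carlo calibration of the planted node-strength effects.

    Holds an ensemble of control-like noisy matrices (deterministic given
    the config seed).  ``sd`` is the between-subject SD of the strength AUC
    per thalamic node; ``sensitivity(node, delta)`` is the finite-difference
    AUC response to shifting all of a node's incident edges by ``delta`` in
    Fisher-z space, averaged over the ensemble — evaluated at the operating
    shift magnitude because the response is nonlinear (shifted edges also
    change rank in the density thresholding).
    """

    def __init__(self, config: CohortConfig, atlas: RegionAtlas,
                 mean_z: np.ndarray, n_sens: int = 20):
        rng = _rng(config, 99)
        n = len(atlas)
        self.atlas = atlas
        self.thal = atlas.thalamic_labels
        self.thal_idx = {t: atlas.index(t) for t in self.thal}
        n_cal = config.calibration_samples
        self._noise = [
            _symmetric_noise(rng, n, config.edge_noise_sd)
            for _ in range(n_cal)
        ]
        self._mean_z = mean_z
        base = np.empty((n_cal, len(self.thal)))
        idx = list(self.thal_idx.values())
        for k, nz in enumerate(self._noise):
            base[k] = strength_auc_matrix(np.tanh(mean_z + nz))[idx]
        self._base = base
        self.sd = dict(zip(self.thal, base.std(axis=0, ddof=1)))
        self._n_sens = min(n_sens, n_cal)

    def sensitivity(self, node: str, delta: float) -> float:
        ti = self.thal_idx[node]
        col = self.thal.index(node)
        diffs = []
        for k in range(self._n_sens):
            z = self._mean_z + self._noise[k]
            z[ti, :] += delta
            z[:, ti] += delta
            z[ti, ti] = 0.0
            auc = strength_auc_matrix(np.tanh(z))[ti]
            diffs.append((auc - self._base[k, col]) / delta)
            z[ti, :] -= delta
            z[:, ti] -= delta
        return float(np.mean(diffs))

    def solve_shift(self, node: str, cohen_d: float) -> float:
        """z-shift realizing a Cohen d on the node's Z-scored AUC.

        One fixed-point refinement: probe at a small shift, solve, then
        re-evaluate the sensitivity at the solved magnitude.
        """
        target = cohen_d * self.sd[node]
        probe = np.sign(cohen_d) * 0.005 if cohen_d else 0.005
        delta = target / self.sensitivity(node, probe)
        return target / self.sensitivity(node, delta)


def generate_connectivity(
    subjects: pd.DataFrame, config: CohortConfig, truth: GroundTruth,
    atlas: RegionAtlas | None = None,
) -> dict[str, np.ndarray]:
    """One symmetric 122x122 correlation matrix per subject.

    Generated in Fisher-z space (population mean + subject noise + planted
    incident-edge shifts) and back-transformed with tanh, which keeps every
    entry in (-1, 1) by construction.
    """
    if atlas is None:
        atlas = default_atlas()
    mean_z = mean_connectivity_z(atlas)
    if not np.isfinite(mean_z).all():
        raise ValueError("population mean matrix contains non-finite values")
    rng = _rng(config, 3)
    n = len(atlas)
    out = {}
    for sid, row in subjects.iterrows():
        z = mean_z + _symmetric_noise(rng, n, config.edge_noise_sd)
        if row["focus_side"] in ("L", "R"):
            for (selector, lat, node), delta in truth.edge_shift_z.items():
                if not _selector_mask(subjects.loc[[sid]], selector).iloc[0]:
                    continue
                node_hemi = node.split("_", 1)[0]
                ipsi = node_hemi == row["focus_side"]
                if (lat == "ipsi") != ipsi:
                    continue
                ti = atlas.index(node)
                z[ti, :] += delta
                z[:, ti] += delta
                z[ti, ti] = 0.0
        m = np.tanh(z)
        np.fill_diagonal(m, 0.0)
        out[sid] = m
    return out


# ---------------------------------------------------------------------------
# batch effects


def inject_batch_effects(
    table: pd.DataFrame,
    batch: pd.Series,
    offset,
    scale,
    target_batch: str,
) -> pd.DataFrame:
    """Apply an additive offset and multiplicative scale to one batch.

    Scaling is around the target batch's own per-feature mean, so the batch
    mean moves by exactly ``offset`` and the batch SD by exactly ``scale``.
    ``offset``/``scale`` may be scalars or per-feature arrays.
    """
    batch = batch.reindex(table.index)
    known = set(batch.dropna().unique())
    if target_batch not in known:
        raise ValueError(
            f"unknown batch label {target_batch!r}; present: {sorted(known)}"
        )
    out = table.astype(float).copy()
    sel = (batch == target_batch).to_numpy()
    if sel.sum() == 0:
        return out
    block = out.loc[sel]
    m_b = block.mean(axis=0)
    out.loc[sel] = m_b + (block - m_b) * scale + offset
    return out


def apply_batch_effects_to_volumes(
    volumes: pd.DataFrame,
    subjects: pd.DataFrame,
    config: CohortConfig,
    truth: GroundTruth,
) -> pd.DataFrame:
    be = config.batch_effect
    feats = volume_feature_names()
    _, sds = _volume_feature_params(config)
    offsets = np.array([be.volume_offset_sd * sds[f] for f in feats])
    out = volumes.copy()
    out[feats] = inject_batch_effects(
        volumes[feats], subjects["scanner_batch"], offsets, be.volume_scale,
        be.target_batch,
    )
    for f, o in zip(feats, offsets):
        truth.batch_offsets[("volume", f)] = float(o)
    return out


def apply_batch_effects_to_matrices(
    matrices: dict[str, np.ndarray],
    subjects: pd.DataFrame,
    config: CohortConfig,
    truth: GroundTruth,
) -> dict[str, np.ndarray]:
    be = config.batch_effect
    sids = list(matrices)
    n = next(iter(matrices.values())).shape[0]
    iu, ju = np.triu_indices(n, k=1)
    table = pd.DataFrame({sid: matrices[sid][iu, ju] for sid in sids}).T
    shifted = inject_batch_effects(
        table, subjects["scanner_batch"].reindex(table.index),
        be.edge_offset, be.edge_scale, be.target_batch,
    )
    truth.batch_offsets[("edges", "all")] = float(be.edge_offset)
    out = {}
    for sid in sids:
        m = np.zeros((n, n))
        m[iu, ju] = shifted.loc[sid].to_numpy()
        m += m.T
        out[sid] = m
    return out
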