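"""Normative scoring: eTIV adjustment, control GLM, hemisphere-wise Z, laterality.

The measure tables (thalamic volumes or strength AUCs) move through a fixed
stage order: harmonized -> eTIV-adjusted (volumes only) -> Z-scored against
a control-fitted age/sex GLM (the W-score convention) -> relabeled as
ipsilateral/contralateral to the seizure focus.  Z-scoring is strictly
hemisphere-matched: a right-sided feature is scored against the control
distribution of the same right-sided feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

STAGES = ("raw", "harmonized", "etiv_adjusted", "z")


def adjust_for_etiv(
    table: pd.DataFrame,
    etiv: pd.Series,
    control_mask: pd.Series,
    method: str = "residual",
) -> pd.DataFrame:
    """Remove the eTIV-predicted component from each volume feature.

    residual method (default): regress each feature on eTIV in controls,
    subtract the predicted deviation from everyone, re-center on the
    control mean.  The ratio method (feature / eTIV x control mean eTIV) is
    available behind the switch.
    """
    etiv = etiv.reindex(table.index)
    if etiv.isna().any():
        missing = table.index[etiv.isna()][:5].tolist()
        raise ValueError(f"missing eTIV for subjects {missing}")
    control_mask = control_mask.reindex(table.index).astype(bool)
    if method == "ratio":
        ref = etiv[control_mask].mean()
        return table.mul(ref / etiv, axis=0)
    if method != "residual":
        raise ValueError(f"unknown eTIV adjustment method {method!r}")
    e = etiv.to_numpy(float)
    ec = e[control_mask.to_numpy()]
    e_center = ec.mean()
    denom = ((ec - e_center) ** 2).sum()
    out = {}
    for col in table.columns:
        y = table[col].to_numpy(float)
        yc = y[control_mask.to_numpy()]
        slope = (
            ((ec - e_center) * (yc - yc.mean())).sum() / denom
            if denom > 0 else 0.0
        )
        out[col] = y - slope * (e - e_center)
    return pd.DataFrame(out, index=table.index)


@dataclass
class NormativeModel:
    """Per-feature control GLM (intercept + age + sex) and residual scale."""

    feature_names: list[str]
    intercept: np.ndarray
    age_slope: np.ndarray
    sex_offset: np.ndarray   # effect of male (sex coded F=0, M=1)
    resid_sd: np.ndarray
    age_center: float

    def predict(self, age: pd.Series, sex: pd.Series) -> pd.DataFrame:
        a = age.to_numpy(float)[:, None] - self.age_center
        s = (sex == "M").to_numpy(float)[:, None]
        pred = self.intercept[None, :] + a * self.age_slope[None, :] \
            + s * self.sex_offset[None, :]
        return pd.DataFrame(pred, index=age.index, columns=self.feature_names)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "feature_names": self.feature_names,
                    "intercept": self.intercept.tolist(),
                    "age_slope": self.age_slope.tolist(),
                    "sex_offset": self.sex_offset.tolist(),
                    "resid_sd": self.resid_sd.tolist(),
                    "age_center": self.age_center,
                },
                fh,
            )


def fit_normative_model(
    control_table: pd.DataFrame,
    age: pd.Series,
    sex: pd.Series,
) -> NormativeModel:
    """Least-squares age+sex GLM per feature, fitted on controls only."""
    if len(control_table) < 10:
        raise ValueError("need at least 10 controls to fit the normative model")
    age = age.reindex(control_table.index).astype(float)
    sex = sex.reindex(control_table.index)
    sex_num = (sex == "M").astype(float)
    if sex_num.nunique() < 2:
        raise ValueError("both sexes must be present in the control sample")
    age_center = float(age.mean())
    X = np.column_stack([
        np.ones(len(control_table)),
        age.to_numpy() - age_center,
        sex_num.to_numpy(),
    ])
    Y = control_table.to_numpy(float)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    dof = max(len(control_table) - X.shape[1], 1)
    sd = np.sqrt((resid**2).sum(axis=0) / dof)
    if (sd <= 0).any():
        bad = [c for c, s in zip(control_table.columns, sd) if s <= 0]
        raise ValueError(f"zero residual SD for features {bad}")
    return NormativeModel(
        feature_names=list(control_table.columns),
        intercept=B[0],
        age_slope=B[1],
        sex_offset=B[2],
        resid_sd=sd,
        age_center=age_center,
    )


def zscore_to_controls(
    table: pd.DataFrame,
    model: NormativeModel,
    age: pd.Series,
    sex: pd.Series,
) -> pd.DataFrame:
    """Z = (value - control GLM prediction) / control residual SD."""
    missing = [c for c in table.columns if c not in model.feature_names]
    if missing:
        raise KeyError(f"features absent from the normative model: {missing}")
    pred = model.predict(age.reindex(table.index), sex.reindex(table.index))
    sd = pd.Series(model.resid_sd, index=model.feature_names)
    return (table - pred[table.columns]) / sd[table.columns]


def relabel_laterality(
    z_table: pd.DataFrame,
    focus_side: pd.Series,
) -> pd.DataFrame:
    """Re-key hemisphere features as ipsi/contra relative to the seizure focus.

    Input columns are '<L|R>_<subdivision>'.  Patients with a left focus map
    left -> ipsi and right -> contra; right-focus patients are mirrored.
    Subjects without a focus side (controls) are excluded; feed them the
    left/right table instead.  Relabeling an already-relabeled table is the
    identity.
    """
    if all(c.startswith(("ipsi_", "contra_")) for c in z_table.columns):
        return z_table.copy()
    focus = focus_side.reindex(z_table.index)
    bad = focus.isin(["none"]) | focus.isna()
    if bad.any():
        raise ValueError(
            f"subjects without a focus side cannot be relabeled: "
            f"{z_table.index[bad][:5].tolist()}"
        )
    subs = sorted({c.split('_', 1)[1] for c in z_table.columns})
    out = {}
    for sub in subs:
        left = z_table[f"L_{sub}"]
        right = z_table[f"R_{sub}"]
        is_left = (focus == "L").to_numpy()
        out[f"ipsi_{sub}"] = np.where(is_left, left, right)
        out[f"contra_{sub}"] = np.where(is_left, right, left)
    return pd.DataFrame(out, index=z_table.index)


class StagedTable:
    """A measure table with enforced stage ordering.

    Stages advance monotonically along ``raw -> harmonized ->
    etiv_adjusted -> z``; applying a stage out of order raises.
    """

    def __init__(self, table: pd.DataFrame, stage: str = "raw"):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        self.table = table
        self.stage = stage

    def advance(self, table: pd.DataFrame, stage: str) -> "StagedTable":
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise ValueError(
                f"stage {stage!r} cannot follow {self.stage!r}; order is "
                + " -> ".join(STAGES)
            )
        return StagedTable(table, stage)

    def to_long(self) -> pd.DataFrame:
        long = self.table.reset_index().melt(
            id_vars=self.table.index.name or "index",
            var_name="feature", value_name="value",
        )
        long["stage"] = self.stage
        return long
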