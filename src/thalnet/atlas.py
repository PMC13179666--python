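"""Region atlas: 122 nodes = 8 thalamic subdivisions + 104 Harvard-Oxford-style regions.

The thalamus is represented by four anatomical subdivisions per hemisphere,
obtained by grouping THOMAS nuclei:

* anterior  — anteroventral nucleus (AV)
* lateral   — ventral anterior (VA), ventral lateral anterior (VLa),
              ventral lateral posterior (VLP), ventral posterolateral (VPL)
* medial    — centromedian (CM), mediodorsal/parafascicular (MD-Pf)
* pulvinar  — pulvinar (Pul)

The remaining 114 regions are 57 bilateral cortical/subcortical labels in the
Harvard-Oxford naming style.  The exact label list is a synthetic stand-in
with the right cardinality and hemisphere structure; the thalamic mapping is
the real one.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

SUBDIVISIONS = ("anterior", "lateral", "medial", "pulvinar")
HEMISPHERES = ("L", "R")

#: THOMAS nucleus label -> thalamic subdivision
THOMAS_TO_SUBDIVISION = {
    "AV": "anterior",
    "VA": "lateral",
    "VLa": "lateral",
    "VLP": "lateral",
    "VPL": "lateral",
    "CM": "medial",
    "MD-Pf": "medial",
    "Pul": "pulvinar",
}


def map_thomas_to_subdivision(nucleus_label: str) -> str:
    """Map a THOMAS nucleus label to its thalamic subdivision.

    Raises
    ------
    KeyError
        If the label is not a THOMAS nucleus label.
    """
    try:
        return THOMAS_TO_SUBDIVISION[nucleus_label]
    except KeyError:
        raise KeyError(
            f"unknown THOMAS nucleus label {nucleus_label!r}; "
            f"expected one of {sorted(THOMAS_TO_SUBDIVISION)}"
        ) from None


@dataclass(frozen=True)
class Region:
    label: str
    hemisphere: str  # 'L' or 'R'
    region_class: str  # 'thalamic' or 'other'
    subdivision: str | None  # for thalamic regions


class RegionAtlas:
    """The 122-region atlas with thalamic subdivision annotations."""

    def __init__(self, table: pd.DataFrame):
        required = {"label", "hemisphere", "region_class", "subdivision"}
        if not required.issubset(table.columns):
            raise ValueError(f"atlas table needs columns {sorted(required)}")
        if table["label"].duplicated().any():
            raise ValueError("atlas labels must be unique")
        self.table = table.reset_index(drop=True)
        self.labels = list(table["label"])
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        thal = table[table["region_class"] == "thalamic"]
        if len(thal) != 8:
            raise ValueError(f"expected 8 thalamic regions, got {len(thal)}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def thalamic_label(self, subdivision: str, hemisphere: str) -> str:
        if subdivision not in SUBDIVISIONS:
            raise KeyError(f"unknown subdivision {subdivision!r}")
        if hemisphere not in HEMISPHERES:
            raise KeyError(f"unknown hemisphere {hemisphere!r}")
        return f"{hemisphere}_thal_{subdivision}"

    def thalamic_index(self, subdivision: str, hemisphere: str) -> int:
        return self.index(self.thalamic_label(subdivision, hemisphere))

    @property
    def thalamic_labels(self) -> list[str]:
        return list(self.table.loc[self.table["region_class"] == "thalamic", "label"])

    @property
    def other_labels(self) -> list[str]:
        return list(self.table.loc[self.table["region_class"] == "other", "label"])

    def hemisphere(self, label: str) -> str:
        return self.table.loc[self._index[label], "hemisphere"]

    def homologue(self, label: str) -> str:
        """Label of the same region in the opposite hemisphere."""
        if label.startswith("L_"):
            return "R_" + label[2:]
        if label.startswith("R_"):
            return "L_" + label[2:]
        raise KeyError(f"label {label!r} has no hemisphere prefix")


def default_atlas() -> RegionAtlas:
    """Load the packaged 122-region atlas."""
    with resources.files("thalnet.data").joinpath("atlas.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", keep_default_na=False)
    table["subdivision"] = table["subdivision"].replace("", None)
    return RegionAtlas(table)


# 57 bilateral non-thalamic base labels (cortical + subcortical),
# Harvard-Oxford naming style; 57 x 2 + 8 thalamic = 122 regions.
_OTHER_BASE_LABELS = [
    "frontal_pole",
    "insular_cortex",
    "superior_frontal_gyrus",
    "middle_frontal_gyrus",
    "inferior_frontal_gyrus_pars_triangularis",
    "inferior_frontal_gyrus_pars_opercularis",
    "precentral_gyrus",
    "temporal_pole",
    "superior_temporal_gyrus_anterior",
    "superior_temporal_gyrus_posterior",
    "middle_temporal_gyrus_anterior",
    "middle_temporal_gyrus_posterior",
    "middle_temporal_gyrus_temporooccipital",
    "inferior_temporal_gyrus_anterior",
    "inferior_temporal_gyrus_posterior",
    "inferior_temporal_gyrus_temporooccipital",
    "postcentral_gyrus",
    "superior_parietal_lobule",
    "supramarginal_gyrus_anterior",
    "supramarginal_gyrus_posterior",
    "angular_gyrus",
    "lateral_occipital_cortex_superior",
    "lateral_occipital_cortex_inferior",
    "intracalcarine_cortex",
    "frontal_medial_cortex",
    "juxtapositional_lobule",
    "subcallosal_cortex",
    "paracingulate_gyrus",
    "cingulate_gyrus_anterior",
    "cingulate_gyrus_posterior",
    "precuneous_cortex",
    "cuneal_cortex",
    "frontal_orbital_cortex",
    "parahippocampal_gyrus_anterior",
    "parahippocampal_gyrus_posterior",
    "lingual_gyrus",
    "temporal_fusiform_cortex_anterior",
    "temporal_fusiform_cortex_posterior",
    "temporal_occipital_fusiform_cortex",
    "occipital_fusiform_gyrus",
    "frontal_operculum_cortex",
    "central_opercular_cortex",
    "parietal_operculum_cortex",
    "planum_polare",
    "heschls_gyrus",
    "planum_temporale",
    "supracalcarine_cortex",
    "occipital_pole",
    "paracentral_lobule",
    "inferior_frontal_gyrus_pars_orbitalis",
    "medial_orbitofrontal_cortex",
    "entorhinal_cortex",
    "hippocampus",
    "amygdala",
    "accumbens",
    "caudate",
    "putamen",
]


def build_atlas_table() -> pd.DataFrame:
    """Construct the default atlas table (the packaged TSV is written from this)."""
    rows = []
    for hemi in HEMISPHERES:
        for sub in SUBDIVISIONS:
            rows.append(
                {
                    "label": f"{hemi}_thal_{sub}",
                    "hemisphere": hemi,
                    "region_class": "thalamic",
                    "subdivision": sub,
                }
            )
    for hemi in HEMISPHERES:
        for base in _OTHER_BASE_LABELS:
            rows.append(
                {
                    "label": f"{hemi}_{base}",
                    "hemisphere": hemi,
                    "region_class": "other",
                    "subdivision": "",
                }
            )
    return pd.DataFrame(rows)
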