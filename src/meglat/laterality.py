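"""Laterality indices of regional band power and control-baseline correction.

The laterality index of a region r and band f is

    LI = (P_L - P_R) / (P_L + P_R)

where P_L, P_R are the regional oscillatory powers of the left and right
hemisphere. LI lies in (-1, 1); +1 means fully left-dominant power. Healthy
brains are not symmetric, so before group comparisons the healthy-control
group's mean LI per band x region is subtracted from each patient's LI
("baseline correction"), putting the patient groups on a scale where 0 means
"lateralized like a control". Corrected values lie in (-2, 2).

Tables are handled as tidy pandas DataFrames. A power table is long-format
with columns (subject_id, group, age, band, region, hemisphere, power); an LI
table has columns (subject_id, group, age, band, region, li). The 28-feature
matrix used by the classifier orders columns band-major: delta..hfo, and
frontal, temporal, parietal, occipital within each band.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, GROUP_CTR, REGIONS, feature_names

__all__ = [
    "compute_li",
    "li_table",
    "li_matrix",
    "ctr_baseline",
    "baseline_correct",
]

#: Powers below this are treated as non-positive: the index is undefined there.
POWER_EPS = 1e-12


def compute_li(p_left: float, p_right: float) -> float:
    """Scalar laterality index (P_L - P_R) / (P_L + P_R) for positive powers."""
    if p_left < POWER_EPS or p_right < POWER_EPS:
        raise ValueError(
            f"laterality index requires strictly positive powers, got "
            f"({p_left!r}, {p_right!r})"
        )
    return (p_left - p_right) / (p_left + p_right)


def _check_complete(wide: pd.DataFrame, bands, regions) -> None:
    expected = {(b, r) for b in bands for r in regions}
    missing = []
    for sid, sub in wide.groupby(level="subject_id", sort=False):
        have = set(zip(sub.index.get_level_values("band"), sub.index.get_level_values("region")))
        gap = expected - have
        if gap or sub[["L", "R"]].isna().any().any():
            nan_cells = {
                (b, r)
                for (sid_, b, r), row in sub.iterrows()
                if row[["L", "R"]].isna().any()
            }
            missing.append((sid, sorted(gap | nan_cells)))
    if missing:
        desc = "; ".join(f"{sid}: {cells}" for sid, cells in missing[:5])
        raise ValueError(f"incomplete power table, missing cells — {desc}")


def li_table(
    powers: pd.DataFrame,
    bands: tuple[str, ...] = BAND_NAMES,
    regions: tuple[str, ...] = REGIONS,
) -> pd.DataFrame:
    """Per-subject laterality indices from a long-format power table.

    Every subject must have a complete bands x regions x {L, R} set of strictly
    positive powers; missing cells are reported explicitly.
    """
    required = {"subject_id", "band", "region", "hemisphere", "power"}
    if not required.issubset(powers.columns):
        raise ValueError(f"power table must have columns {sorted(required)}")
    bad = powers[powers["power"] < POWER_EPS]
    if len(bad):
        raise ValueError(
            f"non-positive power for subject(s) {sorted(bad['subject_id'].unique())[:5]}"
        )
    wide = powers.pivot_table(
        index=["subject_id", "band", "region"],
        columns="hemisphere",
        values="power",
        aggfunc="first",
    )
    for h in ("L", "R"):
        if h not in wide.columns:
            wide[h] = np.nan
    _check_complete(wide, bands, regions)
    out = wide.reset_index()
    out["li"] = (out["L"] - out["R"]) / (out["L"] + out["R"])
    meta_cols = [c for c in ("group", "age") if c in powers.columns]
    if meta_cols:
        meta = powers.drop_duplicates("subject_id").set_index("subject_id")[meta_cols]
        out = out.join(meta, on="subject_id")
    out = out[["subject_id", *meta_cols, "band", "region", "li"]]
    out.attrs["baseline_corrected"] = False
    return out


def li_matrix(
    li: pd.DataFrame,
    bands: tuple[str, ...] = BAND_NAMES,
    regions: tuple[str, ...] = REGIONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(subjects x 28 feature matrix, per-subject metadata), band-major columns."""
    X = li.pivot_table(index="subject_id", columns=["band", "region"], values="li")
    cols = [(b, r) for b in bands for r in regions]
    X = X.reindex(columns=pd.MultiIndex.from_tuples(cols, names=["band", "region"]))
    if X.isna().any().any():
        raise ValueError("LI table incomplete: cannot form the 28-feature matrix")
    X.columns = feature_names(bands, regions)
    meta_cols = [c for c in ("group", "age") if c in li.columns]
    meta = li.drop_duplicates("subject_id").set_index("subject_id")[meta_cols]
    return X, meta.loc[X.index]


def ctr_baseline(li: pd.DataFrame, ctr_group: str = GROUP_CTR) -> pd.DataFrame:
    """Healthy-control mean LI per band x region (columns band, region, mean_li)."""
    ctr = li[li["group"] == ctr_group]
    if ctr["subject_id"].nunique() < 2:
        raise ValueError("baseline requires at least 2 control subjects")
    base = (
        ctr.groupby(["band", "region"], sort=False, observed=True)["li"]
        .mean()
        .rename("mean_li")
        .reset_index()
    )
    return base


def baseline_correct(li: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Subtract the control-group mean LI from each entry, per band x region."""
    if li.attrs.get("baseline_corrected"):
        raise ValueError("LI table is already baseline-corrected")
    merged = li.merge(baseline, on=["band", "region"], how="left", validate="m:1")
    if merged["mean_li"].isna().any():
        missing = merged.loc[merged["mean_li"].isna(), ["band", "region"]]
        raise ValueError(f"baseline missing cells: {missing.drop_duplicates().values.tolist()}")
    out = li.copy()
    out["li"] = (merged["li"] - merged["mean_li"]).to_numpy()
    out.attrs["baseline_corrected"] = True
    return out
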