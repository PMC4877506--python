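"""Stem morphometry, inter-operator reliability and the stem-volume ANOVA.

A stem ROI is a single-slice binary mask; its volume is the voxel count
times the voxel volume and its centre of mass the unweighted mean of the
non-zero voxel-centre world coordinates (optionally pushed through an
affine into a standard space). Group morphometry uses a split-plot ANOVA
with Tract (IFOF, UF) and Hemisphere (left, right) as within-subject
factors and Sex between subjects; both within factors have two levels, so
no sphericity correction applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dissection import StemROI
from .geometry import voxel_to_world

#: Published normative group-mean stem centres of mass in MNI space (mm)
#: and mean stem volumes (mm^3) for the two ventral association tracts,
#: 60-subject cohort, primary operator. Used for coordinate-consistency
#: checks of inter-stem contrasts.
REFERENCE_STEM_TABLE = pd.DataFrame(
    [
        {"tract": "IFOF", "hemisphere": "left", "volume_mm3": 82.5,
         "x": -30.6, "y": 0.5, "z": -8.0},
        {"tract": "IFOF", "hemisphere": "right", "volume_mm3": 100.3,
         "x": 31.7, "y": 0.6, "z": -7.4},
        {"tract": "UF", "hemisphere": "left", "volume_mm3": 74.0,
         "x": -33.3, "y": -2.4, "z": -16.2},
        {"tract": "UF", "hemisphere": "right", "volume_mm3": 93.9,
         "x": 33.6, "y": -1.2, "z": -17.2},
    ]
).set_index(["tract", "hemisphere"])


@dataclass
class StemSummary:
    tract: str
    hemisphere: str
    operator: str
    volume_mm3: float
    center_of_mass: np.ndarray
    subject: int = 0


def stem_summary(stem: StemROI, voxel_volume: float,
                 to_standard: np.ndarray | None = None,
                 subject: int = 0) -> StemSummary:
    """Volume and unweighted centre of mass of a stem ROI."""
    idx = np.argwhere(stem.mask)
    if len(idx) == 0:
        raise ValueError("stem mask is empty")
    com = voxel_to_world(idx, stem.affine).mean(axis=0)
    if to_standard is not None:
        to_standard = np.asarray(to_standard, dtype=float)
        com = to_standard[:3, :3] @ com + to_standard[:3, 3]
    return StemSummary(stem.tract_tag, stem.hemisphere, stem.operator,
                       float(len(idx) * voxel_volume), com, subject=subject)


def com_distance(a, b):
    """Euclidean distance (mm) and per-axis absolute differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    delta = np.abs(a - b)
    return float(np.linalg.norm(a - b)), delta


def interoperator_report(stems_op1, stems_op2) -> pd.DataFrame:
    """Reliability of stem delineation between two operators.

    Inputs are matched lists of StemSummary (same subjects/tracts/
    hemispheres). Per tract x hemisphere: mean +/- SD of signed volume
    differences (op1 - op2), a paired two-sided t-test on volumes, and
    mean +/- SD of centre-of-mass Euclidean distances.
    """
    def key(s):
        return (s.subject, s.tract, s.hemisphere)

    d1 = {key(s): s for s in stems_op1}
    d2 = {key(s): s for s in stems_op2}
    unmatched = set(d1) ^ set(d2)
    if unmatched:
        raise ValueError(f"unmatched stem keys: {sorted(unmatched)}")
    rows = []
    frame = pd.DataFrame([
        {"tract": s.tract, "hemisphere": s.hemisphere, "subject": s.subject,
         "v1": s.volume_mm3, "v2": d2[key(s)].volume_mm3,
         "dist": com_distance(s.center_of_mass,
                              d2[key(s)].center_of_mass)[0]}
        for s in stems_op1])
    for (tract, hemi), g in frame.groupby(["tract", "hemisphere"]):
        dv = (g.v1 - g.v2).to_numpy()
        if len(g) > 1 and np.ptp(dv) > 0:
            t_p = float(stats.ttest_rel(g.v1, g.v2).pvalue)
        else:
            t_p = 1.0 if np.allclose(dv, 0) else np.nan
        rows.append({
            "tract": tract, "hemisphere": hemi, "n": len(g),
            "volume_diff_mean": float(dv.mean()),
            "volume_diff_sd": float(dv.std(ddof=1)) if len(g) > 1 else 0.0,
            "volume_ttest_p": t_p,
            "com_dist_mean": float(g.dist.mean()),
            "com_dist_sd": float(g.dist.std(ddof=1)) if len(g) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def _effect_f(ss_eff, df_eff, ss_err, df_err):
    """F and p with the degenerate-variance guards the morphometry needs."""
    if ss_eff <= 1e-300:
        return 0.0, 1.0
    ms_eff = ss_eff / df_eff
    if ss_err <= 1e-300:
        return np.inf, 0.0
    ms_err = ss_err / df_err
    f = ms_eff / ms_err
    return float(f), float(stats.f.sf(f, df_eff, df_err))


def stem_volume_anova(volumes: pd.DataFrame) -> pd.DataFrame:
    """Split-plot ANOVA of stem volumes.

    ``volumes`` has columns subject, sex, tract, hemisphere, volume, with
    exactly one observation per subject x tract x hemisphere cell (2 x 2
    within design) and one sex per subject. Returns an ANOVA table with F
    and p per effect; within effects are tested against their own
    subject-interaction error strata (classical univariate decomposition).
    """
    df = volumes.copy()
    needed = {"subject", "sex", "tract", "hemisphere", "volume"}
    if not needed <= set(df.columns):
        raise ValueError(f"missing columns: {sorted(needed - set(df.columns))}")
    cells = df.groupby(["subject", "tract", "hemisphere"]).size()
    if (cells != 1).any() or df.tract.nunique() != 2 \
            or df.hemisphere.nunique() != 2:
        raise ValueError("need exactly one observation per subject x "
                         "tract x hemisphere over a full 2 x 2 design")
    subj_sex = df.groupby("subject")["sex"].nunique()
    if (subj_sex != 1).any():
        raise ValueError("each subject must have exactly one sex label")

    df = df.copy()
    df["g"] = df["sex"]
    y = df.set_index(["subject", "tract", "hemisphere"])["volume"]
    subjects = sorted(df.subject.unique())
    groups = df.groupby("subject")["sex"].first()
    tracts = sorted(df.tract.unique())
    hemis = sorted(df.hemisphere.unique())
    n = len(subjects)
    glabels = sorted(groups.unique())
    n_g = groups.value_counts()

    gm = y.mean()
    m_s = y.groupby("subject").mean()
    m_g = {g: m_s[groups[groups == g].index].mean() for g in glabels}
    m_t = y.groupby("tract").mean()
    m_h = y.groupby("hemisphere").mean()
    m_th = y.groupby(["tract", "hemisphere"]).mean()
    m_st = y.groupby(["subject", "tract"]).mean()
    m_sh = y.groupby(["subject", "hemisphere"]).mean()
    m_gt = df.groupby(["g", "tract"])["volume"].mean()
    m_gh = df.groupby(["g", "hemisphere"])["volume"].mean()
    m_gth = df.groupby(["g", "tract", "hemisphere"])["volume"].mean()

    # between-subject stratum
    ss_sex = 4 * sum(n_g[g] * (m_g[g] - gm) ** 2 for g in glabels)
    ss_err_between = 4 * sum((m_s[s] - m_g[groups[s]]) ** 2 for s in subjects)

    # tract stratum
    ss_tract = 2 * n * sum((m_t[t] - gm) ** 2 for t in tracts)
    ss_tract_sex = 2 * sum(
        n_g[g] * (m_gt[(g, t)] - m_g[g] - m_t[t] + gm) ** 2
        for g in glabels for t in tracts)
    ss_err_tract = 2 * sum(
        (m_st[(s, t)] - m_s[s] - m_gt[(groups[s], t)] + m_g[groups[s]]) ** 2
        for s in subjects for t in tracts)

    # hemisphere stratum
    ss_hemi = 2 * n * sum((m_h[h] - gm) ** 2 for h in hemis)
    ss_hemi_sex = 2 * sum(
        n_g[g] * (m_gh[(g, h)] - m_g[g] - m_h[h] + gm) ** 2
        for g in glabels for h in hemis)
    ss_err_hemi = 2 * sum(
        (m_sh[(s, h)] - m_s[s] - m_gh[(groups[s], h)] + m_g[groups[s]]) ** 2
        for s in subjects for h in hemis)

    # tract x hemisphere stratum
    ss_th = n * sum(
        (m_th[(t, h)] - m_t[t] - m_h[h] + gm) ** 2
        for t in tracts for h in hemis)
    ss_th_sex = sum(
        n_g[g] * ((m_gth[(g, t, h)] - m_gt[(g, t)] - m_gh[(g, h)] + m_g[g])
                  - (m_th[(t, h)] - m_t[t] - m_h[h] + gm)) ** 2
        for g in glabels for t in tracts for h in hemis)
    ss_err_th = sum(
        (y[(s, t, h)] - m_st[(s, t)] - m_sh[(s, h)] + m_s[s]
         - (m_gth[(groups[s], t, h)] - m_gt[(groups[s], t)]
            - m_gh[(groups[s], h)] + m_g[groups[s]])) ** 2
        for s in subjects for t in tracts for h in hemis)

    ge = len(glabels) - 1
    df_err = n - len(glabels)
    rows = []
    for name, ss, dfe, ss_err, df_e in [
        ("sex", ss_sex, ge, ss_err_between, df_err),
        ("tract", ss_tract, 1, ss_err_tract, df_err),
        ("tract:sex", ss_tract_sex, ge, ss_err_tract, df_err),
        ("hemisphere", ss_hemi, 1, ss_err_hemi, df_err),
        ("hemisphere:sex", ss_hemi_sex, ge, ss_err_hemi, df_err),
        ("tract:hemisphere", ss_th, 1, ss_err_th, df_err),
        ("tract:hemisphere:sex", ss_th_sex, ge, ss_err_th, df_err),
    ]:
        f, p = _effect_f(ss, dfe, ss_err, df_e)
        rows.append({"effect": name, "ss": float(ss), "df": dfe,
                     "ss_error": float(ss_err), "df_error": df_e,
                     "F": f, "p": p})
    return pd.DataFrame(rows)


def reference_stem_contrasts() -> pd.DataFrame:
    """Inter-stem coordinate contrasts from the published group means.

    Per hemisphere: the per-axis absolute differences and the Euclidean
    distance between the mean IFOF and UF stem centres of mass.
    """
    rows = []
    for hemi in ("left", "right"):
        a = REFERENCE_STEM_TABLE.loc[("IFOF", hemi), ["x", "y", "z"]]
        b = REFERENCE_STEM_TABLE.loc[("UF", hemi), ["x", "y", "z"]]
        dist, delta = com_distance(a.to_numpy(float), b.to_numpy(float))
        rows.append({"hemisphere": hemi, "dx": delta[0], "dy": delta[1],
                     "dz": delta[2], "euclidean": dist})
    return pd.DataFrame(rows)
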