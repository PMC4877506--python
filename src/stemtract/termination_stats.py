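"""Cortical-termination quantification and group statistics.

For each subject and tract, streamline endpoints reaching cortical grey
matter are tallied per region and hemisphere. The normalized termination
density score of a region is

    NTDS_REG = (endpoints of the tract ending in REG)
               / (total left + right tract streamlines),

so premature ("broken") terminations depress the scores without leaving
the denominator. A false-positive reference region (one the tract is known
not to reach) sets a presence threshold over the cohort,

    Threshold_FP = mean(NTDS_FP) + 2 * SD(NTDS_FP),

adjusted scores are ``NTDS - Threshold_FP`` (negatives retained so paired
tests keep a full sample), presence means an adjusted score above zero,
territories are regions whose adjusted scores beat zero by a one-sided
Wilcoxon signed-rank test under Bonferroni correction, and laterality uses
the asymmetry index ``(Right - Left) / (Right + Left)`` per region tested
against zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dissection import ExtractionResult
from .tract_io import LabelTable


@dataclass
class TerminationTable:
    """One subject-tract's endpoint tallies."""

    counts: pd.DataFrame           # columns: region, hemisphere, count (CGM)
    total_streamlines: int
    broken: dict                   # side -> count of non-cortical endpoints
    excluded: dict                 # side -> endpoints in discarded lobes
    subject: int = 0
    tract: str = ""

    def __post_init__(self):
        if (self.counts["count"] < 0).any():
            raise ValueError("negative endpoint counts")
        if self.counts["count"].sum() > 2 * self.total_streamlines:
            raise ValueError("more endpoints than 2 x streamlines")


def _anterior_is_end0(lab0, lab1, y0, y1, side_lut):
    """Decide which stored endpoint is the anterior one.

    Prefer the label's terminal-side annotation; fall back to world y
    (more anterior = larger y) when neither or both ends are annotated
    with the same side.
    """
    s0 = side_lut[lab0]
    s1 = side_lut[lab1]
    if s0 == "anterior_set" and s1 != "anterior_set":
        return True
    if s1 == "anterior_set" and s0 != "anterior_set":
        return False
    if s0 == "posterior_set" and s1 != "posterior_set":
        return False
    if s1 == "posterior_set" and s0 != "posterior_set":
        return True
    return y0 >= y1


def tally_terminations(extraction: ExtractionResult, table: LabelTable,
                       subject: int = 0, tract: str = "") -> TerminationTable:
    """Tally extracted-streamline endpoints into a TerminationTable.

    Each cortical (CGM) endpoint not flagged excluded increments its
    region/hemisphere cell; endpoints flagged broken increment the broken
    tally of their side; endpoints in discarded lobes (insula,
    subcortical) increment the excluded tally. The denominator is the
    number of extracted streamlines over both hemispheres.
    """
    ep = extraction.endpoints
    side_lut = table.lookup_array("terminal_side", fill="none")
    name_lut = table.lookup_array("name", fill="")
    hemi_lut = table.lookup_array("hemisphere", fill="")
    tissue_lut = table.lookup_array("tissue", fill="")
    counts: dict = {}
    broken = {"anterior": 0, "posterior": 0}
    excluded = {"anterior": 0, "posterior": 0}
    for _, row in ep.iterrows():
        ant_is_0 = _anterior_is_end0(row.end0_label, row.end1_label,
                                     row.end0_y, row.end1_y, side_lut)
        ends = [("anterior" if ant_is_0 else "posterior", "end0"),
                ("posterior" if ant_is_0 else "anterior", "end1")]
        for side, end in ends:
            lab = int(row[f"{end}_label"])
            if row[f"{end}_excluded"]:
                excluded[side] += 1
            elif row[f"{end}_broken"] or lab == 0 or tissue_lut[lab] != "CGM":
                broken[side] += 1
            else:
                hemi = hemi_lut[lab]
                name = name_lut[lab]
                # region identity is hemisphere-independent
                if name.endswith(f"_{hemi}"):
                    name = name[: -len(hemi) - 1]
                counts[(name, hemi)] = counts.get((name, hemi), 0) + 1
    frame = pd.DataFrame(
        [{"region": r, "hemisphere": h, "count": c}
         for (r, h), c in sorted(counts.items())],
        columns=["region", "hemisphere", "count"])
    return TerminationTable(frame, len(ep), broken, excluded,
                            subject=subject, tract=tract)


def cohort_counts(tables: list) -> pd.DataFrame:
    """Stack per-subject TerminationTables into a long cohort frame."""
    rows = []
    for t in tables:
        for _, r in t.counts.iterrows():
            rows.append({"subject": t.subject, "tract": t.tract,
                         "region": r.region, "hemisphere": r.hemisphere,
                         "count": int(r["count"]),
                         "total": t.total_streamlines})
    return pd.DataFrame(rows, columns=["subject", "tract", "region",
                                       "hemisphere", "count", "total"])


def compute_ntds(counts: pd.DataFrame, all_regions=None,
                 hemispheres=("left", "right")) -> pd.DataFrame:
    """NTDS per subject x region x hemisphere from a long count frame.

    Region/hemisphere cells with no endpoints get NTDS 0 (the complete
    grid is needed so cohort statistics see true zeros). ``all_regions``
    may extend the grid beyond regions that ever received a count.
    """
    if (counts["total"] <= 0).any():
        raise ValueError("total streamline count must be > 0")
    regions = set(counts.region.unique())
    if all_regions is not None:
        regions |= set(all_regions)
    subjects = sorted(counts.subject.unique())
    totals = counts.groupby("subject")["total"].first()
    grid = pd.MultiIndex.from_product(
        [subjects, sorted(regions), hemispheres],
        names=["subject", "region", "hemisphere"])
    dense = (counts.groupby(["subject", "region", "hemisphere"])["count"]
             .sum().reindex(grid, fill_value=0).reset_index())
    dense["ntds"] = dense["count"] / dense.subject.map(totals)
    if ((dense.ntds < 0) | (dense.ntds > 1)).any():
        raise ValueError("NTDS outside [0, 1]")
    return dense[["subject", "region", "hemisphere", "ntds"]]


@dataclass
class ThresholdResult:
    fp_region: str
    mean: float
    sd: float
    threshold: float
    per_hemisphere: dict | None = None


def fp_threshold(ntds: pd.DataFrame, fp_region: str,
                 per_hemisphere: bool = False) -> ThresholdResult:
    """Presence threshold: mean + 2 x sample SD of the FP region's NTDS.

    Pooled over hemispheres by default; ``per_hemisphere=True`` computes a
    separate threshold per hemisphere.
    """
    sel = ntds[ntds.region == fp_region]
    if sel.empty:
        raise ValueError(f"FP region {fp_region!r} absent from NTDS table")
    if sel.subject.nunique() < 2:
        raise ValueError("threshold needs at least 2 subjects")
    vals = sel.ntds.to_numpy()
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    per = None
    if per_hemisphere:
        per = {}
        for h, grp in sel.groupby("hemisphere"):
            v = grp.ntds.to_numpy()
            per[h] = float(v.mean() + 2 * v.std(ddof=1))
    return ThresholdResult(fp_region, mean, sd, mean + 2 * sd, per)


def adjust_ntds(ntds: pd.DataFrame, thr: ThresholdResult) -> pd.DataFrame:
    """Adjusted scores NTDS - threshold, negatives retained."""
    out = ntds.copy()
    if thr.per_hemisphere:
        out["adj"] = out.ntds - out.hemisphere.map(thr.per_hemisphere)
    else:
        out["adj"] = out.ntds - thr.threshold
    return out


def presence_percentages(adj: pd.DataFrame) -> pd.DataFrame:
    """Percent of subjects with adjusted score > 0, per region/hemisphere."""
    def pct(g):
        return 100.0 * (g.adj > 0).sum() / g.subject.nunique()
    out = (adj.groupby(["region", "hemisphere"])
           .apply(pct, include_groups=False).rename("percent").reset_index())
    return out


def _wilcoxon_greater(values: np.ndarray):
    """One-sided (greater) signed-rank p; zeros dropped; exact for n<=25."""
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    if len(v) == 0:
        return 1.0, True
    ties = len(np.unique(np.abs(v))) < len(v)
    method = "exact" if (len(v) <= 25 and not ties) else "approx"
    res = stats.wilcoxon(v, alternative="greater", zero_method="wilcox",
                         method=method)
    return float(res.pvalue), False


def territory_test(adj: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per region/hemisphere: is the adjusted score distribution > 0?

    One-sided Wilcoxon signed-rank against 0 with zeros dropped; Bonferroni
    threshold alpha / (number of region-hemisphere cells tested). Regions
    whose adjusted scores are all zero are degenerate (p = 1).
    """
    groups = list(adj.groupby(["region", "hemisphere"]))
    n_small = [g.subject.nunique() for _, g in groups]
    if any(n < 5 for n in n_small):
        raise ValueError("territory test needs >= 5 subjects per cell")
    n_tests = len(groups)
    bonf = alpha / n_tests
    rows = []
    for (region, hemi), g in groups:
        p, degenerate = _wilcoxon_greater(g.adj.to_numpy())
        rows.append({"region": region, "hemisphere": hemi, "p": p,
                     "degenerate": degenerate,
                     "significant": bool(p < bonf)})
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = n_tests
    out.attrs["bonferroni_alpha"] = bonf
    return out


def asymmetry_index(left, right):
    """(Right - Left)/(Right + Left); NaN where both sides are zero."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if np.any(left < 0) or np.any(right < 0):
        raise ValueError("asymmetry index needs non-negative scores")
    total = left + right
    with np.errstate(invalid="ignore", divide="ignore"):
        ai = np.where(total > 0, (right - left) / total, np.nan)
    if ai.ndim == 0:
        return float(ai)
    return ai


def asymmetry_table(ntds: pd.DataFrame) -> pd.DataFrame:
    """Per subject x region asymmetry index from the NTDS frame."""
    wide = ntds.pivot_table(index=["subject", "region"],
                            columns="hemisphere", values="ntds")
    for h in ("left", "right"):
        if h not in wide:
            wide[h] = 0.0
    ai = asymmetry_index(wide["left"].to_numpy(), wide["right"].to_numpy())
    out = wide.reset_index()[["subject", "region"]]
    out["ai"] = ai
    return out


def asymmetry_test(ai: pd.DataFrame, alpha: float = 0.05,
                   method: str = "t", min_n: int = 5) -> pd.DataFrame:
    """Two-sided one-sample location test of asymmetry indexes against 0.

    ``method`` 't' (default) or 'wilcoxon'. Regions with fewer than
    ``min_n`` non-missing values are skipped (tested=False). Bonferroni
    correction runs over the regions actually tested.
    """
    rows = []
    for region, g in ai.groupby("region"):
        v = g.ai.dropna().to_numpy()
        if len(v) < min_n:
            rows.append({"region": region, "n": len(v), "mean_ai": np.nan,
                         "p": np.nan, "tested": False, "degenerate": False})
            continue
        degenerate = False
        if np.allclose(v, 0.0):
            p = 1.0
            degenerate = True
        elif np.std(v) == 0:
            p = 0.0
            degenerate = True
        elif method == "t":
            p = float(stats.ttest_1samp(v, 0.0).pvalue)
        elif method == "wilcoxon":
            nz = v[v != 0]
            ties = len(np.unique(np.abs(nz))) < len(nz)
            m = "exact" if (len(nz) <= 25 and not ties) else "approx"
            p = float(stats.wilcoxon(nz, zero_method="wilcox",
                                     method=m).pvalue)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"region": region, "n": len(v),
                     "mean_ai": float(np.mean(v)), "p": p, "tested": True,
                     "degenerate": degenerate})
    out = pd.DataFrame(rows)
    tested = out.tested.sum()
    bonf = alpha / tested if tested else np.nan
    out["significant"] = out.tested & (out.p < bonf)
    out.attrs["n_tests"] = int(tested)
    out.attrs["bonferroni_alpha"] = bonf
    return out
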