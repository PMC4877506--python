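"""Stem-based virtual dissection of association tracts.

Stages mirror the anatomical workflow: (1) *prepare* a whole-brain
tractogram by removing streamline families that cannot belong to long
association pathways (sub-10-mm fragments, grey-matter-confined fragments,
superficial U-fibres that never enter deep white matter, cerebellar and
interhemispheric streamlines); (2) *expose* a tract's stem by additionally
hiding streamlines terminating in regions that shroud it; (3) define a
single-slice stem ROI at the bundle's waist (drawn externally or suggested
by :func:`suggest_stem_slice`); (4) *extract* the tract from the original
tractogram as every streamline passing through the stem ROI, subject to
per-tract exclusion rules, and label its endpoints on the dilated atlas.

Streamline-to-voxel assignment everywhere uses the exact plane-crossing
voxel walk from :mod:`stemtract.geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import nearest_voxel, polyline_length, traverse_voxels_batch
from .tract_io import LabelVolume, Tractogram

PREP_RULES = ["short", "gm_confined", "u_fiber", "cerebellar", "interhemispheric"]

# endpoint families that hide each stem during exposure
EXPOSURE_RULES = {
    "IFOF": {"endpoint_lobes": {"insula"}, "endpoint_regions": {"temporal_pole"}},
    "UF": {"endpoint_lobes": {"insula"}, "endpoint_regions": {"superior_temporal"}},
}

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}
_ORIENTATION_AXIS = {"coronal": 1, "axial": 2}


@dataclass
class PrepParams:
    min_length_mm: float = 10.0
    sampling_step_mm: float | None = None  # used by sampled traversal only

    def __post_init__(self):
        if self.min_length_mm <= 0:
            raise ValueError("min_length_mm must be > 0")


@dataclass
class StreamlineClassification:
    length_mm: float
    endpoint_labels: tuple           # (first point, last point), dilated atlas
    tissues: frozenset
    lobes: frozenset
    crosses_midsagittal: bool
    enters_cerebellum_brainstem: bool


@dataclass
class StemROI:
    """Single-slice binary stem mask aligned with the tractogram grid."""

    mask: np.ndarray
    affine: np.ndarray
    orientation: str                 # 'coronal' or 'axial'
    tract_tag: str = ""
    hemisphere: str = ""
    operator: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.orientation not in _ORIENTATION_AXIS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        idx = np.argwhere(self.mask)
        if len(idx) == 0:
            raise ValueError("stem mask is empty")
        axis = _ORIENTATION_AXIS[self.orientation]
        slices = np.unique(idx[:, axis])
        if len(slices) != 1:
            raise ValueError(
                f"stem mask spans {len(slices)} slices along its axis; "
                "must be single-slice")
        self.slice_index = int(slices[0])

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ExtractionRules:
    """Per-tract extraction constraints applied after stem selection."""

    exclusion_labels: set = field(default_factory=set)
    exclusion_plane: tuple | None = None     # (axis 'x'|'y'|'z', coord mm, side)
    discard_terminal_lobes: set = field(
        default_factory=lambda: {"insula", "subcortical"})
    discard_broken: bool = False

    def __post_init__(self):
        if self.exclusion_plane is not None:
            axis, _, side = self.exclusion_plane
            if axis not in _AXIS_INDEX:
                raise ValueError(f"plane axis must be x/y/z, got {axis!r}")
            if side not in {"greater", "less"}:
                raise ValueError(f"plane side must be greater/less, got {side!r}")


def streamline_length(s) -> float:
    """Euclidean polyline length in mm."""
    return polyline_length(np.asarray(s, dtype=float))


# ---------------------------------------------------------------------------
# batch classification


def compute_traversal(t: Tractogram, affine: np.ndarray):
    """Precompute (voxel, owner) traversal rows reusable across stages."""
    return traverse_voxels_batch(t.streamlines, affine)


def _streamline_flags(t: Tractogram, vol: LabelVolume, traversal=None):
    """Vectorised per-streamline traversal summaries.

    Returns a dict of arrays over streamlines: tissue membership flags,
    cerebellum entry, midline crossing, plus the raw (voxel, owner) rows.
    """
    n = len(t)
    vox, owner = traversal if traversal is not None \
        else traverse_voxels_batch(t.streamlines, vol.affine)
    labels = vol.labels_at_voxels(vox)
    tissue_lut = vol.table.lookup_array("tissue", fill="")
    lobe_lut = vol.table.lookup_array("lobe", fill="")
    tissues = tissue_lut[labels]
    lobes = lobe_lut[labels]

    def scatter_any(cond):
        out = np.zeros(n, dtype=bool)
        out[owner[cond]] = True
        return out

    flags = {
        "any_cgm": scatter_any(tissues == "CGM"),
        "any_swm": scatter_any(tissues == "SWM"),
        "any_dwm": scatter_any(tissues == "DWM"),
        "any_other_tissue": scatter_any((tissues == "other") | (labels == 0)),
        "enters_cerebellum": scatter_any(lobes == "cerebellum_brainstem"),
    }
    crosses = np.zeros(n, dtype=bool)
    for i, s in enumerate(t.streamlines):
        x = np.asarray(s)[:, 0]
        crosses[i] = bool(np.any(x[:-1] * x[1:] < 0) or np.any(x == 0.0))
    flags["crosses_midsagittal"] = crosses
    flags["length"] = np.array(
        [polyline_length(np.asarray(s)) for s in t.streamlines])
    return flags, (vox, owner, labels)


def _endpoint_labels(t: Tractogram, dilated: LabelVolume):
    if len(t) == 0:
        empty = np.empty(0, dtype=int)
        return empty, empty
    firsts = np.array([s[0] for s in t.streamlines])
    lasts = np.array([s[-1] for s in t.streamlines])
    lab0 = dilated.labels_at_voxels(nearest_voxel(firsts, dilated.affine))
    lab1 = dilated.labels_at_voxels(nearest_voxel(lasts, dilated.affine))
    return lab0.astype(int), lab1.astype(int)


def classify_streamline(s, vol: LabelVolume, dilated: LabelVolume,
                        params: PrepParams | None = None
                        ) -> StreamlineClassification:
    """Full classification of a single streamline (see module docs)."""
    t = Tractogram([np.asarray(s, dtype=float)], affine=vol.affine,
                   voxel_size=vol.voxel_size)
    flags, (vox, owner, labels) = _streamline_flags(t, vol)
    lab0, lab1 = _endpoint_labels(t, dilated)
    tissue_lut = vol.table.lookup_array("tissue", fill="")
    lobe_lut = vol.table.lookup_array("lobe", fill="")
    nz = labels != 0
    return StreamlineClassification(
        length_mm=float(flags["length"][0]),
        endpoint_labels=(int(lab0[0]), int(lab1[0])),
        tissues=frozenset(tissue_lut[labels[nz]]),
        lobes=frozenset(lobe_lut[labels[nz]]),
        crosses_midsagittal=bool(flags["crosses_midsagittal"][0]),
        enters_cerebellum_brainstem=bool(flags["enters_cerebellum"][0]),
    )


# ---------------------------------------------------------------------------
# preparation


@dataclass
class PrepareResult:
    tractogram: Tractogram
    tally: dict
    kept_indices: np.ndarray
    removal_rule: np.ndarray   # per input streamline: rule name or ''


def prepare_tractogram(t: Tractogram, vol: LabelVolume,
                       dilated: LabelVolume | None = None,
                       params: PrepParams | None = None,
                       traversal=None) -> PrepareResult:
    """Remove non-association streamline families from a whole tractogram.

    Rules apply in a fixed order, each removal attributed to the first
    matching rule: (1) length < 10 mm; (2) confined to cortical GM;
    (3) U-shaped — never enters deep white matter (traversal within
    CGM+SWM); (4) enters cerebellum/brainstem; (5) crosses the
    mid-sagittal plane.
    """
    params = params or PrepParams()
    tally = {r: 0 for r in PREP_RULES}
    if len(t) == 0:
        return PrepareResult(t, tally, np.array([], dtype=int),
                             np.array([], dtype=object))
    flags, _ = _streamline_flags(t, vol, traversal)
    in_brain = flags["any_cgm"] | flags["any_swm"] | flags["any_dwm"]
    rule = np.full(len(t), "", dtype=object)
    short = flags["length"] < params.min_length_mm
    gm_confined = (~short) & flags["any_cgm"] & ~flags["any_swm"] \
        & ~flags["any_dwm"]
    u_fiber = (~short) & (~gm_confined) & flags["any_swm"] \
        & ~flags["any_dwm"] & in_brain
    cereb = (~short) & (~gm_confined) & (~u_fiber) \
        & flags["enters_cerebellum"]
    inter = (~short) & (~gm_confined) & (~u_fiber) & (~cereb) \
        & flags["crosses_midsagittal"]
    for name, mask in zip(PREP_RULES, [short, gm_confined, u_fiber, cereb,
                                       inter]):
        rule[mask] = name
        tally[name] = int(mask.sum())
    kept = np.nonzero(rule == "")[0]
    return PrepareResult(t.subset(kept), tally, kept, rule)


# ---------------------------------------------------------------------------
# stem exposure


def expose_stem(prepared: Tractogram, dilated: LabelVolume,
                tract: str) -> Tractogram:
    """Hide streamlines whose endpoints shroud the given tract's stem.

    For the IFOF: endpoints in the insula or temporal pole; for the UF:
    endpoints in the insula or superior temporal gyrus. The result is a
    visualization/drawing aid — extraction always goes back to the original
    tractogram.
    """
    if tract not in EXPOSURE_RULES:
        raise ValueError(f"unknown tract {tract!r}")
    if len(prepared) == 0:
        return prepared
    rules = EXPOSURE_RULES[tract]
    table = dilated.table
    bad = set()
    for lobe in rules["endpoint_lobes"]:
        bad.update(table.ids_where(lobe=lobe).tolist())
    for region in rules["endpoint_regions"]:
        names = table.frame.name.astype(str)
        bad.update(table.frame.index[names.str.startswith(region)].tolist())
    lab0, lab1 = _endpoint_labels(prepared, dilated)
    drop = np.isin(lab0, sorted(bad)) | np.isin(lab1, sorted(bad))
    return prepared.subset(np.nonzero(~drop)[0])


# ---------------------------------------------------------------------------
# stem slice suggestion


def suggest_stem_slice(exposed: Tractogram, vol: LabelVolume,
                       orientation: str, search_range):
    """Find the bundle's waist: the slice with fewest occupied voxels.

    ``search_range`` is an iterable of candidate slice indices along the
    orientation axis. Slices intersected by no streamline are excluded
    (reported with occupancy 0 in the profile); ties break to the lowest
    slice index. Returns ``(slice_index, candidate_mask, profile)`` where
    the mask holds that slice's occupied voxels and the profile is a
    DataFrame (slice, n_voxels).
    """
    slices = sorted(int(s) for s in search_range)
    if not slices:
        raise ValueError("empty search range")
    if len(exposed) == 0:
        raise ValueError("no streamlines to profile")
    axis = _ORIENTATION_AXIS[orientation]
    vox, owner = traverse_voxels_batch(exposed.streamlines, vol.affine)
    shape = np.array(vol.grid.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    vox = vox[inside]
    occupied = np.unique(vox, axis=0)
    counts = []
    for s in slices:
        counts.append(int((occupied[:, axis] == s).sum()))
    profile = pd.DataFrame({"slice": slices, "n_voxels": counts})
    nonzero = profile[profile.n_voxels > 0]
    if nonzero.empty:
        raise ValueError("no streamline crosses the search range")
    best = int(nonzero.loc[nonzero.n_voxels.idxmin(), "slice"])
    mask = np.zeros(vol.grid.shape, dtype=bool)
    sel = occupied[occupied[:, axis] == best]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return best, mask, profile


# ---------------------------------------------------------------------------
# extraction


@dataclass
class ExtractionResult:
    tractogram: Tractogram
    endpoints: pd.DataFrame
    tally: dict


def extract_tract(original: Tractogram, stem: StemROI,
                  rules: ExtractionRules, vol: LabelVolume,
                  dilated: LabelVolume, traversal=None) -> ExtractionResult:
    """Extract every streamline passing through the stem ROI.

    Works on the *original* whole-brain tractogram. Streamlines touching
    ``rules.exclusion_labels`` or extending beyond ``rules.exclusion_plane``
    are dropped; endpoints are labelled on the dilated atlas; endpoints in
    ``discard_terminal_lobes`` are kept but flagged excluded-from-analysis;
    endpoints not reaching cortical grey matter are flagged broken.
    """
    if stem.n_voxels == 0:
        raise ValueError("stem mask is empty")
    if len(original) == 0:
        empty = pd.DataFrame(columns=[
            "orig_index", "end0_label", "end0_excluded", "end0_broken",
            "end1_label", "end1_excluded", "end1_broken", "broken"])
        return ExtractionResult(original, empty, {
            "kept": 0, "excluded_by_label": 0, "excluded_by_plane": 0,
            "broken": 0})
    vox, owner = traversal if traversal is not None \
        else traverse_voxels_batch(original.streamlines, stem.affine)
    shape = np.array(stem.mask.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    in_mask = np.zeros(len(vox), dtype=bool)
    v = vox[inside]
    in_mask[inside] = stem.mask[v[:, 0], v[:, 1], v[:, 2]]
    passes = np.zeros(len(original), dtype=bool)
    passes[owner[in_mask]] = True

    labels = vol.labels_at_voxels(vox)
    touches_excl = np.zeros(len(original), dtype=bool)
    if rules.exclusion_labels:
        hit = np.isin(labels, sorted(rules.exclusion_labels))
        touches_excl[owner[hit]] = True

    beyond_plane = np.zeros(len(original), dtype=bool)
    if rules.exclusion_plane is not None:
        ax, coord, side = rules.exclusion_plane
        d = _AXIS_INDEX[ax]
        for i in np.nonzero(passes)[0]:
            c = np.asarray(original.streamlines[i])[:, d]
            beyond_plane[i] = bool(
                np.any(c > coord) if side == "greater" else np.any(c < coord))

    excl_label = passes & touches_excl
    excl_plane = passes & ~touches_excl & beyond_plane
    kept_mask = passes & ~touches_excl & ~beyond_plane
    kept = np.nonzero(kept_mask)[0]

    kept_tract = original.subset(kept)
    lab0, lab1 = _endpoint_labels(kept_tract, dilated)
    table = dilated.table
    lobe_lut = table.lookup_array("lobe", fill="")
    tissue_lut = table.lookup_array("tissue", fill="")
    ep = pd.DataFrame({"orig_index": kept})
    for end, lab, sl_pts in [
        ("end0", lab0, [np.asarray(s)[0] for s in kept_tract.streamlines]),
        ("end1", lab1, [np.asarray(s)[-1] for s in kept_tract.streamlines]),
    ]:
        lobes = lobe_lut[lab]
        tissues = tissue_lut[lab]
        ep[f"{end}_label"] = lab
        ep[f"{end}_excluded"] = np.isin(
            lobes, sorted(rules.discard_terminal_lobes))
        ep[f"{end}_broken"] = (lab == 0) | ((tissues != "CGM")
                                            & ~ep[f"{end}_excluded"])
        pts = np.array(sl_pts) if sl_pts else np.zeros((0, 3))
        ep[f"{end}_y"] = pts[:, 1] if len(pts) else []
    ep["broken"] = ep.end0_broken | ep.end1_broken
    if rules.discard_broken:
        keep_rows = ~ep.broken
        kept_tract = kept_tract.subset(np.nonzero(keep_rows.to_numpy())[0])
        ep = ep[keep_rows].reset_index(drop=True)
    tally = {
        "kept": len(kept_tract),
        "excluded_by_label": int(excl_label.sum()),
        "excluded_by_plane": int(excl_plane.sum()),
        "broken": int(ep.broken.sum()),
    }
    return ExtractionResult(kept_tract, ep, tally)
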