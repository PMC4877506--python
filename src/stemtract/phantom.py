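"""Synthetic labelled phantoms and streamline cohorts with exact ground truth.

The phantom emulates, at desk scale, the anatomy the dissection pipeline
operates on: two hemispheres separated by the mid-sagittal plane ``x = 0``,
each with an anterior (frontal) and a posterior (occipito-temporo-parietal)
bank of cortical grey-matter (CGM) gyral blocks, a superficial white-matter
(SWM) layer beneath each bank, a connected deep white-matter (DWM) core,
an insular and a subcortical block carved into the core, and a combined
cerebellum/brainstem block below. Association-tract streamlines run from an
anterior CGM region through a compact stem ("waist") in the DWM to a
posterior CGM region; every nuisance class the dissection filters target
(U-fibres, GM-confined fragments, sub-10-mm fragments, interhemispheric and
cerebellar streamlines, stem-bypassing decoys, prematurely stopping
"broken" streamlines) is realised geometrically with margins that make its
class decidable exactly, so each filter has a per-streamline oracle.

Coordinates are world mm, RAS+ (x: left->right, y: posterior->anterior,
z: inferior->superior). All randomness flows from ``CohortSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import nearest_voxel, voxel_to_world
from .tract_io import LabelTable, LabelVolume, Tractogram

ANTERIOR_REGIONS = [
    "superior_frontal",
    "middle_frontal",
    "inferior_frontal",
    "orbito_frontal",
    "precentral",
]
POSTERIOR_REGIONS = [
    "superior_parietal",
    "middle_occipital",
    "lingual",
    "superior_temporal",
    "middle_temporal",
    "temporal_pole",
]
REGION_LOBE = {
    "superior_frontal": "frontal",
    "middle_frontal": "frontal",
    "inferior_frontal": "frontal",
    "orbito_frontal": "frontal",
    "precentral": "frontal",
    "superior_parietal": "parietal",
    "middle_occipital": "occipital",
    "lingual": "occipital",
    "superior_temporal": "temporal",
    "middle_temporal": "temporal",
    "temporal_pole": "temporal",
}
# label-id layout: left gyral/tissue labels 1..16, right = +20, cerebellum 50
_BASE_IDS = {name: i + 1 for i, name in enumerate(ANTERIOR_REGIONS + POSTERIOR_REGIONS)}
_BASE_IDS.update({"insula": 12, "swm_anterior": 13, "swm_posterior": 14,
                  "dwm": 15, "subcortical": 16})
RIGHT_OFFSET = 20
CEREBELLUM_ID = 50

TRUE_CLASSES = [
    "tract_whole", "tract_broken", "u_fiber", "gm_confined", "short",
    "interhemispheric", "cerebellar", "stem_bypass",
]


def label_id(region: str, hemisphere: str) -> int:
    base = _BASE_IDS[region]
    return base + RIGHT_OFFSET if hemisphere == "right" else base


@dataclass
class PhantomSpec:
    """Deterministic geometric layout of the phantom label volume."""

    grid_shape: tuple = (60, 72, 60)
    voxel_size: float = 2.0
    cgm_thickness: int = 4   # voxels, anterior/posterior cortical banks
    swm_thickness: int = 4   # voxels, layer between CGM bank and DWM core

    def __post_init__(self):
        nx, ny, nz = self.grid_shape
        c, s = self.cgm_thickness, self.swm_thickness
        self.hemi_i = {"right": (nx // 2 + 2, nx - 4)}
        self.hemi_i["left"] = (nx - 1 - self.hemi_i["right"][1],
                               nx - 1 - self.hemi_i["right"][0])
        self.ant_cgm_j = (ny - 4 - c, ny - 5)
        self.ant_swm_j = (ny - 4 - c - s, ny - 5 - c)
        self.post_cgm_j = (4, 3 + c)
        self.post_swm_j = (4 + c, 3 + c + s)
        self.dwm_j = (4 + c + s, ny - 5 - c - s)
        self.k_range = (16, nz - 5)
        ks = np.arange(self.k_range[0], self.k_range[1] + 1)
        # contiguous k-bands, assigned top (superior) to bottom per list order
        self.ant_bands = _bands(ks, ANTERIOR_REGIONS)
        self.post_bands = _bands(ks, POSTERIOR_REGIONS)

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] *= self.voxel_size
        a[:3, 3] = -self.voxel_size * (np.asarray(self.grid_shape) - 1) / 2.0
        return a

    # -- block bookkeeping (inclusive voxel slabs (i0,i1,j0,j1,k0,k1)) -----

    def region_block(self, region: str, hemisphere: str):
        i0, i1 = self.hemi_i[hemisphere]
        if region in ANTERIOR_REGIONS:
            j0, j1 = self.ant_cgm_j
            k0, k1 = self.ant_bands[region]
        elif region in POSTERIOR_REGIONS:
            j0, j1 = self.post_cgm_j
            k0, k1 = self.post_bands[region]
        else:
            raise KeyError(region)
        return (i0, i1, j0, j1, k0, k1)

    def expected_cgm_voxels(self, region: str) -> int:
        i0, i1, j0, j1, k0, k1 = self.region_block(region, "right")
        return (i1 - i0 + 1) * (j1 - j0 + 1) * (k1 - k0 + 1)

    def insula_block(self, hemisphere: str):
        i1 = self.hemi_i["right"][1]
        jm = (self.dwm_j[0] + self.dwm_j[1]) // 2
        blk = (i1 - 2, i1, jm - 5, jm + 6, 30, 39)
        return blk if hemisphere == "right" else _mirror_i(blk, self.grid_shape[0])

    def subcortical_block(self, hemisphere: str):
        jm = (self.dwm_j[0] + self.dwm_j[1]) // 2
        blk = (self.hemi_i["right"][0] + 4, self.hemi_i["right"][0] + 8,
               jm - 5, jm + 6, 28, 39)
        return blk if hemisphere == "right" else _mirror_i(blk, self.grid_shape[0])

    def cerebellum_block(self):
        nx = self.grid_shape[0]
        return (nx // 2 - 10, nx // 2 + 9, 4, 14, 4, 13)

    # -- default stem geometry --------------------------------------------

    def stem_mask_voxels(self, tract: str, hemisphere: str) -> np.ndarray:
        """2x2 single-slice voxel block defining the designed stem waist."""
        i0r = self.hemi_i["right"][0]
        jm = (self.dwm_j[0] + self.dwm_j[1]) // 2
        if tract == "IFOF":            # coronal slice, mid-DWM
            vox = [(i0r + 8 + a, jm + 1, 44 + b) for a in (0, 1) for b in (0, 1)]
        elif tract == "UF":            # axial slice, ventral DWM
            vox = [(i0r + 14 + a, jm - 5 + b, 24) for a in (0, 1) for b in (0, 1)]
        else:
            raise KeyError(tract)
        vox = np.array(vox)
        if hemisphere == "left":
            vox[:, 0] = self.grid_shape[0] - 1 - vox[:, 0]
        return vox

    def stem_center(self, tract: str, hemisphere: str) -> np.ndarray:
        return voxel_to_world(self.stem_mask_voxels(tract, hemisphere),
                              self.affine).mean(axis=0)


def _bands(ks: np.ndarray, regions) -> dict:
    chunks = np.array_split(ks[::-1], len(regions))
    return {r: (int(c.min()), int(c.max())) for r, c in zip(regions, chunks)}


def _mirror_i(blk, nx):
    i0, i1, j0, j1, k0, k1 = blk
    return (nx - 1 - i1, nx - 1 - i0, j0, j1, k0, k1)


def _fill(grid, blk, value):
    i0, i1, j0, j1, k0, k1 = blk
    grid[i0:i1 + 1, j0:j1 + 1, k0:k1 + 1] = value


def build_phantom_atlas(spec: PhantomSpec | None = None) -> LabelVolume:
    """Deterministic labelled phantom volume with its semantics table."""
    spec = spec or PhantomSpec()
    nx, ny, nz = spec.grid_shape
    grid = np.zeros(spec.grid_shape, dtype=np.int16)
    rows = []
    for hemi in ("left", "right"):
        i0, i1 = spec.hemi_i[hemi]
        # tissue slabs
        _fill(grid, (i0, i1, *spec.ant_swm_j, *spec.k_range),
              label_id("swm_anterior", hemi))
        _fill(grid, (i0, i1, *spec.post_swm_j, *spec.k_range),
              label_id("swm_posterior", hemi))
        _fill(grid, (i0, i1, *spec.dwm_j, *spec.k_range), label_id("dwm", hemi))
        for region in ANTERIOR_REGIONS + POSTERIOR_REGIONS:
            _fill(grid, spec.region_block(region, hemi), label_id(region, hemi))
            rows.append((label_id(region, hemi), f"{region}_{hemi}", hemi,
                         REGION_LOBE[region], "CGM",
                         "anterior_set" if region in ANTERIOR_REGIONS
                         else "posterior_set"))
        _fill(grid, spec.insula_block(hemi), label_id("insula", hemi))
        _fill(grid, spec.subcortical_block(hemi), label_id("subcortical", hemi))
        rows += [
            (label_id("insula", hemi), f"insula_{hemi}", hemi, "insula",
             "CGM", "none"),
            (label_id("swm_anterior", hemi), f"swm_anterior_{hemi}", hemi,
             "other", "SWM", "none"),
            (label_id("swm_posterior", hemi), f"swm_posterior_{hemi}", hemi,
             "other", "SWM", "none"),
            (label_id("dwm", hemi), f"dwm_{hemi}", hemi, "other", "DWM", "none"),
            (label_id("subcortical", hemi), f"subcortical_{hemi}", hemi,
             "subcortical", "other", "none"),
        ]
    _fill(grid, spec.cerebellum_block(), CEREBELLUM_ID)
    rows.append((CEREBELLUM_ID, "cerebellum_brainstem", "midline",
                 "cerebellum_brainstem", "other", "none"))
    table = LabelTable(pd.DataFrame(
        rows, columns=["id", "name", "hemisphere", "lobe", "tissue",
                       "terminal_side"]))
    return LabelVolume(grid, spec.affine, table)


# ---------------------------------------------------------------------------
# cohort specification


def _default_tracts():
    # per-hemisphere termination probability vectors; each side sums to 1.
    # Relative weights follow the group-mean termination density profile of
    # the two ventral association tracts, including their designed left/right
    # asymmetries; 'precentral' (IFOF) and 'superior_parietal' (UF) act as
    # the false-positive reference regions and get near-zero mass.
    return {
        "IFOF": TractSpec(
            name="IFOF",
            orientation="coronal",
            n_streamlines={"left": 250, "right": 250},
            anterior_probs={
                "left": {"inferior_frontal": 0.39, "orbito_frontal": 0.35,
                         "superior_frontal": 0.10, "middle_frontal": 0.14,
                         "precentral": 0.02},
                "right": {"inferior_frontal": 0.49, "orbito_frontal": 0.30,
                          "superior_frontal": 0.075, "middle_frontal": 0.115,
                          "precentral": 0.02},
            },
            posterior_probs={
                "left": {"middle_occipital": 0.19, "lingual": 0.26,
                         "superior_temporal": 0.23, "superior_parietal": 0.16,
                         "middle_temporal": 0.16},
                "right": {"middle_occipital": 0.25, "lingual": 0.22,
                          "superior_temporal": 0.19, "superior_parietal": 0.21,
                          "middle_temporal": 0.13},
            },
        ),
        "UF": TractSpec(
            name="UF",
            orientation="axial",
            n_streamlines={"left": 250, "right": 250},
            anterior_probs={
                "left": {"orbito_frontal": 0.60, "inferior_frontal": 0.32,
                         "middle_frontal": 0.08},
                "right": {"orbito_frontal": 0.84, "inferior_frontal": 0.08,
                          "middle_frontal": 0.08},
            },
            posterior_probs={
                "left": {"temporal_pole": 0.49, "superior_temporal": 0.31,
                         "middle_temporal": 0.18, "superior_parietal": 0.02},
                "right": {"temporal_pole": 0.48, "superior_temporal": 0.37,
                          "middle_temporal": 0.14, "superior_parietal": 0.01},
            },
        ),
    }


@dataclass
class TractSpec:
    """Designed geometry and termination distribution of one tract."""

    name: str
    orientation: str                       # 'coronal' (y slice) or 'axial' (z)
    n_streamlines: dict                    # hemisphere -> count
    anterior_probs: dict                   # hemisphere -> {region: prob}
    posterior_probs: dict

    def __post_init__(self):
        for side in (self.anterior_probs, self.posterior_probs):
            for hemi, probs in side.items():
                total = sum(probs.values())
                if not np.isclose(total, 1.0, atol=1e-9):
                    raise ValueError(
                        f"{self.name}/{hemi}: probabilities sum to {total}")


@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults mirror the study this pipeline models: 60 subjects (half
    female), both ventral tracts in both hemispheres, a 0.2 per-end
    probability of premature ("broken") termination, and a full complement
    of nuisance streamline classes.
    """

    n_subjects: int = 60
    seed: int = 0
    tracts: dict = field(default_factory=_default_tracts)
    broken_fraction: float = 0.2
    decoys: dict = field(default_factory=lambda: {
        "u_fiber": 30, "gm_confined": 30, "short": 30,
        "interhemispheric": 20, "cerebellar": 20, "stem_bypass": 60,
    })
    step_mm: float = 1.0
    stem_jitter_mm: float = 1.4            # in-slice scatter at the waist
    funnel_factor: float = 2.0             # scatter growth 2 slices off-waist
    sexes: list | None = None              # default: alternate F/M

    def sex_of(self, subject_index: int) -> str:
        if self.sexes is not None:
            return self.sexes[subject_index]
        return "F" if subject_index % 2 == 0 else "M"


@dataclass
class GroundTruth:
    """Per-streamline true classes and termination labels."""

    frame: pd.DataFrame

    def __post_init__(self):
        bad = set(self.frame.true_class) - set(TRUE_CLASSES)
        if bad:
            raise ValueError(f"unknown true classes: {sorted(bad)}")


# ---------------------------------------------------------------------------
# streamline construction helpers


def _densify(waypoints, step):
    """Piecewise-linear path through waypoints, vertices preserved."""
    pts = [np.asarray(waypoints[0], dtype=float)]
    for a, b in zip(waypoints[:-1], waypoints[1:]):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        n = max(int(np.ceil(np.linalg.norm(b - a) / step)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        pts.append(a + t * (b - a))
    return np.vstack(pts)


def _block_world(spec, blk, rng, margin=1.0):
    """Uniform random world point inside a voxel slab, 1-voxel margin."""
    lo = voxel_to_world(np.array(blk[::2]), spec.affine)[0]
    hi = voxel_to_world(np.array(blk[1::2]), spec.affine)[0]
    lo = lo + margin * spec.voxel_size
    hi = hi - margin * spec.voxel_size
    return rng.uniform(np.minimum(lo, hi), np.maximum(lo, hi))


def _sample_region(probs: dict, rng) -> str:
    names = sorted(probs)
    p = np.array([probs[n] for n in names])
    return names[rng.choice(len(names), p=p / p.sum())]


class _SubjectBuilder:
    def __init__(self, atlas: LabelVolume, spec: PhantomSpec,
                 cohort: CohortSpec, rng):
        self.atlas = atlas
        self.spec = spec
        self.cohort = cohort
        self.rng = rng
        self.streamlines = []
        self.rows = []
        self.tissue_lut = atlas.table.lookup_array("tissue", fill="")

    def add(self, points, true_class, tract, hemi, ant_label, post_label):
        self.streamlines.append(np.asarray(points, dtype=float))
        self.rows.append({
            "streamline": len(self.streamlines) - 1,
            "true_class": true_class,
            "tract": tract,
            "hemisphere": hemi,
            "anterior_label": int(ant_label),
            "posterior_label": int(post_label),
        })

    # -- tract streamlines -------------------------------------------------

    def tract_streamline(self, tspec: TractSpec, hemi: str,
                         stem_center, bypass=False):
        spec, rng, cohort = self.spec, self.rng, self.cohort
        region_a = _sample_region(tspec.anterior_probs[hemi], rng)
        region_p = _sample_region(tspec.posterior_probs[hemi], rng)
        e_a = _block_world(spec, spec.region_block(region_a, hemi), rng)
        e_p = _block_world(spec, spec.region_block(region_p, hemi), rng)
        center = np.asarray(stem_center, dtype=float)
        w = rng.uniform(-cohort.stem_jitter_mm, cohort.stem_jitter_mm, 2)
        g = cohort.funnel_factor
        gap = 2 * spec.voxel_size  # funnel anchors two slices off the waist
        if tspec.orientation == "coronal":     # slice axis y; in-slice x,z
            s = center + np.array([w[0], 0.0, w[1]])
            pre = center + np.array([g * w[0], gap, g * w[1]])
            post = center + np.array([g * w[0], -gap, g * w[1]])
        else:                                  # axial: slice axis z; x,y
            s = center + np.array([w[0], w[1], 0.0])
            pre = center + np.array([g * w[0], gap + g * w[1], gap])
            post = center + np.array([g * w[0], -gap + g * w[1], gap])
        pts = _densify([e_a, pre, s, post, e_p], cohort.step_mm)
        stem_idx = int(np.argmin(np.linalg.norm(pts - s, axis=1)))
        ant_label = label_id(region_a, hemi)
        post_label = label_id(region_p, hemi)
        if bypass:
            self.add(pts, "stem_bypass", "none", hemi, ant_label, post_label)
            return
        broken_a = rng.random() < cohort.broken_fraction
        broken_p = rng.random() < cohort.broken_fraction
        if broken_a or broken_p:
            pts, ant_label, post_label = self._truncate(
                pts, stem_idx, broken_a, broken_p, ant_label, post_label)
            self.add(pts, "tract_broken", tspec.name, hemi,
                     ant_label, post_label)
        else:
            self.add(pts, "tract_whole", tspec.name, hemi,
                     ant_label, post_label)

    def _truncate(self, pts, stem_idx, broken_a, broken_p, ant, post):
        """Cut one or both ends at a uniform-random interior DWM vertex.

        Cut points keep >= 8 vertices (~8 mm of path) clear of the stem so
        a doubly broken streamline never drops below the 10 mm fragment
        threshold and the class stays decidable.
        """
        vox = nearest_voxel(pts, self.atlas.affine)
        labels = self.atlas.labels_at_voxels(vox)
        tissues = self.tissue_lut[labels]
        start, stop = 0, len(pts)
        margin = 8
        if broken_a:
            cand = np.nonzero(tissues[:stem_idx] == "DWM")[0]
            cand = cand[(cand > 1) & (cand < stem_idx - margin)]
            if len(cand):
                start = int(self.rng.choice(cand))
                ant = 0
        if broken_p:
            cand = stem_idx + 1 + np.nonzero(
                tissues[stem_idx + 1:] == "DWM")[0]
            cand = cand[(cand > stem_idx + margin) & (cand < len(pts) - 2)]
            if len(cand):
                stop = int(self.rng.choice(cand)) + 1
                post = 0
        return pts[start:stop], ant, post

    # -- nuisance classes --------------------------------------------------

    def u_fiber(self, hemi):
        spec, rng = self.spec, self.rng
        a, b = ("superior_frontal", "inferior_frontal")
        e_a = _block_world(spec, spec.region_block(a, hemi), rng)
        e_b = _block_world(spec, spec.region_block(b, hemi), rng)
        # dip into the anterior SWM layer between the two gyri
        j_dip = (spec.ant_swm_j[0] + spec.ant_swm_j[1]) / 2.0
        y_dip = voxel_to_world(np.array([0, j_dip, 0]), spec.affine)[0][1]
        mid = 0.5 * (e_a + e_b)
        mid[1] = y_dip
        pts = _densify([e_a, mid, e_b], self.cohort.step_mm)
        self.add(pts, "u_fiber", "none", hemi,
                 label_id(a, hemi), label_id(b, hemi))

    def gm_confined(self, hemi):
        spec, rng = self.spec, self.rng
        blk = spec.region_block("middle_frontal", hemi)
        p0 = _block_world(spec, blk, rng)
        p1 = _block_world(spec, blk, rng)
        p0[0] = voxel_to_world(np.array([blk[0] + 1, 0, 0]), spec.affine)[0][0]
        p1[0] = voxel_to_world(np.array([blk[1] - 1, 0, 0]), spec.affine)[0][0]
        p0[1] = p1[1]
        p0[2] = p1[2]
        lab = label_id("middle_frontal", hemi)
        self.add(_densify([p0, p1], self.cohort.step_mm),
                 "gm_confined", "none", hemi, lab, lab)

    def short_fragment(self, hemi):
        spec, rng = self.spec, self.rng
        sign = 1.0 if hemi == "right" else -1.0
        p0 = np.array([sign * 22.0, 18.0, 30.0]) + rng.uniform(-1, 1, 3)
        p1 = p0 + np.array([0.0, -4.0, 0.0])
        self.add(np.vstack([p0, p1]), "short", "none", hemi, 0, 0)

    def interhemispheric(self):
        rng = self.rng
        z = 33.0 + rng.uniform(-1, 1)
        y = 1.0 + rng.uniform(-1, 1)
        pts = _densify([np.array([-20.0, y, z]), np.array([20.0, y, z])],
                       self.cohort.step_mm)
        self.add(pts, "interhemispheric", "none", "midline", 0, 0)

    def cerebellar(self, hemi):
        rng = self.rng
        sign = 1.0 if hemi == "right" else -1.0
        p0 = np.array([sign * 14.0, -30.0, -20.0]) + rng.uniform(-1, 1, 3)
        p1 = np.array([sign * 10.0, -53.0, -45.0]) + rng.uniform(-1, 1, 3)
        self.add(_densify([p0, p1], self.cohort.step_mm),
                 "cerebellar", "none", hemi, 0, 0)


def simulate_subject(atlas: LabelVolume, cohort: CohortSpec,
                     subject_index: int, spec: PhantomSpec | None = None):
    """One subject's tractogram plus exact per-streamline ground truth."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng([cohort.seed, subject_index])
    b = _SubjectBuilder(atlas, spec, cohort, rng)
    for tname in sorted(cohort.tracts):
        tspec = cohort.tracts[tname]
        for hemi in ("left", "right"):
            center = spec.stem_center(tname, hemi)
            for _ in range(tspec.n_streamlines.get(hemi, 0)):
                b.tract_streamline(tspec, hemi, center)
    bypass_offset = 6.0  # mm lateral of the stem, outside the 2x2 mask
    for cls in sorted(cohort.decoys):
        count = cohort.decoys[cls]
        for n in range(count):
            hemi = "left" if n % 2 == 0 else "right"
            if cls == "u_fiber":
                b.u_fiber(hemi)
            elif cls == "gm_confined":
                b.gm_confined(hemi)
            elif cls == "short":
                b.short_fragment(hemi)
            elif cls == "interhemispheric":
                b.interhemispheric()
            elif cls == "cerebellar":
                b.cerebellar(hemi)
            elif cls == "stem_bypass":
                tname = sorted(cohort.tracts)[n % len(cohort.tracts)]
                tspec = cohort.tracts[tname]
                center = spec.stem_center(tname, hemi).copy()
                center[0] += bypass_offset if hemi == "right" else -bypass_offset
                b.tract_streamline(tspec, hemi, center, bypass=True)
            else:
                raise ValueError(f"unknown decoy class {cls!r}")
    tractogram = Tractogram(
        b.streamlines,
        voxel_size=np.full(3, spec.voxel_size),
        affine=spec.affine,
        space_tag="phantom",
    )
    return tractogram, GroundTruth(pd.DataFrame(b.rows))


def simulate_cohort(atlas: LabelVolume, cohort: CohortSpec,
                    spec: PhantomSpec | None = None):
    """All subjects of a cohort plus the subject metadata table."""
    spec = spec or PhantomSpec()
    subjects = []
    meta = []
    for s in range(cohort.n_subjects):
        subjects.append(simulate_subject(atlas, cohort, s, spec))
        meta.append({"subject": s, "sex": cohort.sex_of(s)})
    return subjects, pd.DataFrame(meta)


# ---------------------------------------------------------------------------
# per-subject stem ROI masks (operator emulation)


def simulate_stem_mask(spec: PhantomSpec, tract: str, hemisphere: str,
                       rng, operator_shift: float = 0.0,
                       extra_voxels: int | None = None) -> np.ndarray:
    """Grow a plausible hand-drawn single-slice stem mask.

    Starts from the designed 2x2 waist and adds in-slice neighbours at
    random. Right-hemisphere masks receive more voxels by default (the
    rightward stem-volume effect the morphometry ANOVA should detect), and
    ``operator_shift`` adds an in-slice centre jitter emulating a second
    operator.
    """
    vox = spec.stem_mask_voxels(tract, hemisphere)
    axis = 1 if tract == "IFOF" else 2
    if extra_voxels is None:
        mean = 8.0 if hemisphere == "right" else 6.0
        extra_voxels = max(int(round(rng.normal(mean, 2.0))), 0)
    cells = {tuple(v) for v in vox}
    inplane = [a for a in range(3) if a != axis]
    for _ in range(extra_voxels):
        seed_cell = list(cells)[rng.integers(len(cells))]
        step = np.zeros(3, dtype=int)
        step[inplane[rng.integers(2)]] = rng.choice([-1, 1])
        cells.add(tuple(np.array(seed_cell) + step))
    if operator_shift:
        shift = np.zeros(3, dtype=int)
        shift[inplane[rng.integers(2)]] = int(np.sign(rng.normal())) or 1
        if rng.random() < operator_shift:
            cells = {tuple(np.array(c) + shift) for c in cells}
    mask = np.zeros(spec.grid_shape, dtype=bool)
    idx = np.array(sorted(cells))
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return mask


# ---------------------------------------------------------------------------
# count-level cohort generator (statistics-scale studies)


def simulate_termination_counts(
    n_subjects: int,
    n_streamlines: dict,
    anterior_probs: dict,
    posterior_probs: dict,
    broken_fraction: float,
    rng,
) -> pd.DataFrame:
    """Endpoint-count cohorts without streamline geometry.

    Each streamline end survives (reaches cortex) independently with
    probability ``1 - broken_fraction``; surviving ends fall into regions by
    a multinomial draw from the designed per-hemisphere probability vectors.
    Returns a long DataFrame (subject, region, hemisphere, count) plus the
    per-subject total streamline count in the attribute column ``total``.
    The per-streamline geometric route produces identical count laws; this
    generator exists so replicate-heavy statistical studies stay cheap.
    """
    rows = []
    for s in range(n_subjects):
        total = sum(n_streamlines.values())
        for hemi in sorted(n_streamlines):
            n = n_streamlines[hemi]
            for probs in (anterior_probs, posterior_probs):
                names = sorted(probs[hemi])
                p = np.array([probs[hemi][r] for r in names])
                survivors = rng.binomial(n, 1.0 - broken_fraction)
                counts = rng.multinomial(survivors, p / p.sum())
                for r, c in zip(names, counts):
                    rows.append({"subject": s, "region": r, "hemisphere": hemi,
                                 "count": int(c), "total": total})
    return pd.DataFrame(rows)


def simulate_stem_volumes(n_subjects: int, rng, right_scale: float = 1.2,
                          mean_mm3: float = 80.0, sd_mm3: float = 12.0
                          ) -> pd.DataFrame:
    """Subject x tract x hemisphere stem-volume table for the ANOVA.

    Right-hemisphere volumes are scaled by ``right_scale`` (default 20%
    larger, the direction of the known rightward stem-size effect).
    """
    rows = []
    for s in range(n_subjects):
        sex = "F" if s % 2 == 0 else "M"
        base = rng.normal(mean_mm3, sd_mm3)
        for tract in ("IFOF", "UF"):
            for hemi in ("left", "right"):
                v = base * (right_scale if hemi == "right" else 1.0)
                v += rng.normal(0.0, sd_mm3 / 2.0)
                rows.append({"subject": s, "sex": sex, "tract": tract,
                             "hemisphere": hemi, "volume": max(v, 1.0)})
    return pd.DataFrame(rows)
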