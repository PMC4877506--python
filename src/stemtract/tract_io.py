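"""Streamline and labelled-volume I/O.

Streamline files (TRK/TCK) are read and written through ``nibabel``; on
load, coordinates are always expressed in world mm (RAS+), whatever the
on-disk convention (TRK stores corner-origin voxel-mm, converted by
nibabel). Label images are NIfTI-1 integer volumes; their semantics live in
a separate tab-delimited label table (id, name, hemisphere, lobe, tissue,
terminal_side), because NIfTI itself carries no label meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import nearest_voxel

HEMISPHERES = {"left", "right", "midline"}
LOBES = {
    "frontal", "occipital", "temporal", "parietal", "limbic", "insula",
    "subcortical", "cerebellum_brainstem", "other",
}
TISSUES = {"CGM", "SWM", "DWM", "other"}
TERMINAL_SIDES = {"anterior_set", "posterior_set", "none"}

LABEL_TABLE_COLUMNS = ["id", "name", "hemisphere", "lobe", "tissue", "terminal_side"]


@dataclass
class Tractogram:
    """A set of streamlines in world mm with minimal grid metadata."""

    streamlines: list  # list of (n_i, 3) float arrays
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space_tag: str = ""

    def __post_init__(self):
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if not np.all(self.voxel_size > 0):
            raise ValueError("voxel_size must be positive")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")

    def __len__(self):
        return len(self.streamlines)

    def subset(self, indices) -> "Tractogram":
        indices = np.asarray(indices)
        return Tractogram(
            [self.streamlines[i] for i in indices],
            voxel_size=self.voxel_size,
            affine=self.affine,
            space_tag=self.space_tag,
        )


@dataclass
class LabelTable:
    """Per-label anatomical semantics."""

    frame: pd.DataFrame  # indexed by integer label id

    def __post_init__(self):
        df = self.frame
        if df.index.name != "id":
            if "id" in df.columns:
                df = df.set_index("id")
            else:
                raise ValueError("label table needs an 'id' column")
        df.index = df.index.astype(int)
        if df.index.duplicated().any():
            raise ValueError("duplicate label ids")
        if (df.index <= 0).any():
            raise ValueError("label ids must be > 0")
        for col, allowed in [
            ("hemisphere", HEMISPHERES),
            ("lobe", LOBES),
            ("tissue", TISSUES),
            ("terminal_side", TERMINAL_SIDES),
        ]:
            bad = set(df[col]) - allowed
            if bad:
                raise ValueError(f"invalid {col} values: {sorted(bad)}")
        cgm = df[df.tissue == "CGM"]
        if (cgm.terminal_side.isna()).any():
            raise ValueError("every CGM label needs a terminal_side")
        self.frame = df

    @property
    def ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    def lookup_array(self, column: str, fill="") -> np.ndarray:
        """Dense label-id -> attribute array (index 0 and gaps get `fill`)."""
        out = np.full(int(self.frame.index.max()) + 1, fill, dtype=object)
        out[self.frame.index.to_numpy()] = self.frame[column].to_numpy()
        return out

    def ids_where(self, **conditions) -> np.ndarray:
        mask = np.ones(len(self.frame), dtype=bool)
        for col, val in conditions.items():
            vals = val if isinstance(val, (set, list, tuple)) else [val]
            mask &= self.frame[col].isin(vals).to_numpy()
        return self.frame.index.to_numpy()[mask]

    def id_of(self, name: str) -> int:
        hits = self.frame.index[self.frame.name == name]
        if len(hits) != 1:
            raise KeyError(f"label name {name!r} matches {len(hits)} entries")
        return int(hits[0])

    def to_tsv(self, path):
        self.frame.reset_index().to_csv(path, sep="\t", index=False)


@dataclass
class LabelVolume:
    """Integer label grid + affine + semantics table."""

    grid: np.ndarray
    affine: np.ndarray
    table: LabelTable

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("label grid must be integer-typed")
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        present = np.unique(self.grid)
        present = present[present != 0]
        missing = sorted(set(present.tolist()) - set(self.table.ids.tolist()))
        if missing:
            raise ValueError(f"grid labels missing from table: {missing}")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def labels_at_voxels(self, vox: np.ndarray) -> np.ndarray:
        """Labels at integer voxel indices; out-of-grid -> 0."""
        vox = np.atleast_2d(vox)
        shape = np.array(self.grid.shape)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        out = np.zeros(len(vox), dtype=self.grid.dtype)
        v = vox[inside]
        out[inside] = self.grid[v[:, 0], v[:, 1], v[:, 2]]
        return out


def label_at_point(vol: LabelVolume, point) -> int:
    """Label owning a world-mm point (nearest voxel; outside grid -> 0)."""
    vox = nearest_voxel(np.asarray(point, dtype=float), vol.affine)
    return int(vol.labels_at_voxels(vox)[0])


# ---------------------------------------------------------------------------
# file I/O


def read_tractogram(path, format: str | None = None) -> Tractogram:
    """Read a TRK or TCK streamline file into world-mm coordinates.

    ``format`` may be given explicitly ('trk'/'tck'); otherwise the file
    extension decides. Zero streamlines produce a warning, not an error.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"trk", "tck"}:
        raise ValueError(f"unsupported streamline format: {fmt!r}")
    try:
        f = nib.streamlines.load(str(path))
    except Exception as exc:  # malformed header / truncated file
        raise IOError(f"could not parse {path} as {fmt}: {exc}") from exc
    sl = [np.asarray(s, dtype=float) for s in f.tractogram.streamlines]
    if len(sl) == 0:
        warnings.warn(f"{path} contains zero streamlines", stacklevel=2)
    header = f.header
    if fmt == "trk":
        voxel_size = np.asarray(header["voxel_sizes"], dtype=float)
        affine = np.asarray(header["voxel_to_rasmm"], dtype=float)
    else:
        voxel_size = np.ones(3)
        affine = np.eye(4)
    return Tractogram(sl, voxel_size=voxel_size, affine=affine, space_tag=fmt)


def write_tractogram(t: Tractogram, path, format: str | None = None) -> None:
    """Write a Tractogram to TRK or TCK (world-mm in, convention handled)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    sl = [np.asarray(s, dtype=np.float32) for s in t.streamlines]
    tg = nib.streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4))
    if fmt == "trk":
        header = {
            "voxel_to_rasmm": t.affine.astype(np.float32),
            "voxel_sizes": t.voxel_size.astype(np.float32),
            "dimensions": _grid_dims(t),
            "voxel_order": "".join(nib.aff2axcodes(t.affine)),
        }
        nib.streamlines.save(tg, str(path), header=header)
    elif fmt == "tck":
        nib.streamlines.save(tg, str(path))
    else:
        raise ValueError(f"unsupported streamline format: {fmt!r}")


def _grid_dims(t: Tractogram) -> np.ndarray:
    if len(t.streamlines) == 0:
        return np.ones(3, dtype=np.int16)
    pts = np.vstack(t.streamlines)
    inv = np.linalg.inv(t.affine)
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    return (np.floor(vox.max(axis=0)).astype(np.int16) + 2)


def read_label_table(path) -> LabelTable:
    df = pd.read_csv(path, sep="\t")
    missing = set(LABEL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    return LabelTable(df)


def read_label_volume(path, table_path) -> LabelVolume:
    """Load a NIfTI integer label image and its TSV semantics table."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if np.allclose(data, np.round(data)):
            data = np.round(data).astype(np.int32)
        else:
            raise ValueError(f"{path}: voxel data is not integer-valued")
    table = read_label_table(table_path)
    return LabelVolume(data, np.asarray(img.affine), table)


def write_label_volume(vol: LabelVolume, path, table_path=None) -> None:
    img = nib.Nifti1Image(vol.grid.astype(np.int16), vol.affine)
    nib.save(img, str(path))
    if table_path is not None:
        vol.table.to_tsv(table_path)


# ---------------------------------------------------------------------------
# modal dilation


_NEIGHBOR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
)


def modal_dilate(vol: LabelVolume, iterations: int = 1) -> LabelVolume:
    """Grow labels into background by the modal (most frequent) neighbour.

    Each background voxel with at least one non-zero 26-neighbour receives
    the most frequent neighbouring non-zero label; ties break to the lowest
    label id. Already-labelled voxels never change; one pass per iteration.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    grid = vol.grid.copy()
    labels = np.unique(grid)
    labels = labels[labels != 0]
    for _ in range(iterations):
        votes = np.zeros((len(labels),) + grid.shape, dtype=np.uint8)
        for off in _NEIGHBOR_OFFSETS:
            shifted = _shift(grid, off)
            for li, lab in enumerate(labels):
                votes[li] += shifted == lab
        any_vote = votes.sum(axis=0) > 0
        # argmax over ascending label order -> lowest label wins ties
        winner_idx = votes.argmax(axis=0)
        winner = labels[winner_idx]
        update = (grid == 0) & any_vote
        grid = grid.copy()
        grid[update] = winner[update]
    return LabelVolume(grid, vol.affine, vol.table)


def _shift(grid: np.ndarray, offset) -> np.ndarray:
    """Shift a 3-D array by an integer offset, zero-filling the border."""
    out = np.zeros_like(grid)
    src = []
    dst = []
    for o, n in zip(offset, grid.shape):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = grid[tuple(src)]
    return out
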