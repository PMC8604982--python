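"""Literature-based region scoring for coordinate-reported activation contrasts.

Turns a corpus of published activation contrasts (foci in MNI or Talairach
millimetre space, a multiple-comparison correction label, and a
semantics-vs-control contrast class) into per-region scores:

* a *correction-level index* in [-1, 1] rewarding stringently thresholded
  contrasts (voxel-level corrected = 1, cluster-level = 0.5,
  uncorrected = -1; contrasts with unknown correction are excluded from the
  mean),
* a *semantics/control sensitivity index* in [-1, 1] (concrete semantic
  category contrasts = 1, abstract semantic = 0.5, control = -1),
* the componentwise median MNI coordinate of the contributing foci, mapped
  onto a parcel of an integer-labelled atlas volume.

Talairach coordinates are converted to MNI with the Brett piecewise-affine
transform (a rotation about x of 0.05 rad combined with axis zooms of
0.99/0.97/0.92 above the AC plane and 0.99/0.97/0.84 below it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "ContrastRecord",
    "AtlasVolume",
    "CORRECTION_CODES",
    "CLASS_CODES",
    "EXCLUDED",
    "tal2mni",
    "mni2tal",
    "code_correction",
    "code_contrast_class",
    "merge_foci",
    "to_mni",
    "region_scores",
    "records_to_table",
    "table_to_records",
]

CORRECTIONS = ("voxel", "cluster", "uncorrected", "unknown")
CONTRAST_CLASSES = ("concrete_semantic", "abstract_semantic", "control")

#: Numeric codes for the correction-level index.
CORRECTION_CODES = {"voxel": 1.0, "cluster": 0.5, "uncorrected": -1.0}

#: Numeric codes for the semantics/control sensitivity index.
CLASS_CODES = {"concrete_semantic": 1.0, "abstract_semantic": 0.5, "control": -1.0}

#: Sentinel returned for contrasts whose correction level is not reported;
#: such contrasts are excluded from the correction-level mean.
EXCLUDED = None

_COORD_LIMIT_MM = 200.0


# ---------------------------------------------------------------------------
# Brett piecewise-affine Talairach <-> MNI transform
# ---------------------------------------------------------------------------

def _rot_x(rad: float) -> np.ndarray:
    c, s = np.cos(rad), np.sin(rad)
    return np.array(
        [[1, 0, 0, 0], [0, c, s, 0], [0, -s, c, 0], [0, 0, 0, 1]], dtype=float
    )


_M_UP = _rot_x(0.05) @ np.diag([0.99, 0.97, 0.92, 1.0])
_M_DOWN = _rot_x(0.05) @ np.diag([0.99, 0.97, 0.84, 1.0])
_M_UP_INV = np.linalg.inv(_M_UP)
_M_DOWN_INV = np.linalg.inv(_M_DOWN)


def _as_points(coords) -> tuple[np.ndarray, bool]:
    pts = np.asarray(coords, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 3:
        raise ValueError(f"expected (x, y, z) coordinates, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    return pts, single


def _apply_piecewise(pts: np.ndarray, above: np.ndarray, below: np.ndarray) -> np.ndarray:
    hom = np.column_stack([pts, np.ones(len(pts))])
    out = np.where((pts[:, 2] < 0)[:, None], hom @ below.T, hom @ above.T)
    return out[:, :3]


def tal2mni(coords) -> np.ndarray:
    """Convert Talairach mm coordinates to MNI mm coordinates.

    Applies the inverse of the Brett piecewise-affine MNI->Talairach
    transform, selecting the below-AC zoom for points with Talairach z < 0.
    Accepts a single (x, y, z) triple or an (n, 3) array.
    """
    pts, single = _as_points(coords)
    out = _apply_piecewise(pts, _M_UP_INV, _M_DOWN_INV)
    return out[0] if single else out


def mni2tal(coords) -> np.ndarray:
    """Convert MNI mm coordinates to Talairach mm via the Brett transform."""
    pts, single = _as_points(coords)
    out = _apply_piecewise(pts, _M_UP, _M_DOWN)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Contrast records and coding rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastRecord:
    """One published activation contrast with its reported foci.

    ``foci`` are mm coordinates in ``space`` (``"MNI"`` or ``"Talairach"``);
    ``correction`` is the multiple-comparison correction level and
    ``contrast_class`` the semantics/control class of the contrast.
    """

    study_id: str
    contrast_id: str
    foci: tuple = field()
    space: str = "MNI"
    correction: str = "unknown"
    contrast_class: str = "control"

    def __post_init__(self):
        foci = tuple(tuple(float(v) for v in f) for f in self.foci)
        if len(foci) == 0:
            raise ValueError(f"contrast {self.contrast_id!r} has no foci")
        arr = np.asarray(foci)
        if arr.shape[1] != 3 or not np.all(np.isfinite(arr)):
            raise ValueError(f"contrast {self.contrast_id!r} has malformed foci")
        if np.any(np.abs(arr) > _COORD_LIMIT_MM):
            raise ValueError(
                f"contrast {self.contrast_id!r} has foci outside +/-{_COORD_LIMIT_MM} mm"
            )
        if self.space not in ("MNI", "Talairach"):
            raise ValueError(f"unknown coordinate space {self.space!r}")
        if self.correction not in CORRECTIONS:
            raise ValueError(f"unknown correction label {self.correction!r}")
        if self.contrast_class not in CONTRAST_CLASSES:
            raise ValueError(f"unknown contrast class {self.contrast_class!r}")
        object.__setattr__(self, "foci", foci)


def code_correction(correction: str):
    """Code a correction label: voxel -> 1, cluster -> 0.5, uncorrected -> -1.

    ``unknown`` returns the :data:`EXCLUDED` sentinel (``None``): contrasts
    without correction information do not enter the correction-level mean.
    """
    if correction == "unknown":
        return EXCLUDED
    try:
        return CORRECTION_CODES[correction]
    except KeyError:
        raise ValueError(f"unknown correction label {correction!r}") from None


def code_contrast_class(contrast_class: str) -> float:
    """Code a contrast class: concrete_semantic -> 1, abstract_semantic -> 0.5,
    control -> -1."""
    try:
        return CLASS_CODES[contrast_class]
    except KeyError:
        raise ValueError(f"unknown contrast class {contrast_class!r}") from None


def to_mni(record: ContrastRecord) -> ContrastRecord:
    """Return ``record`` with foci in MNI space (Brett transform if needed)."""
    if record.space == "MNI":
        return record
    converted = tuple(tuple(tal2mni(f)) for f in record.foci)
    return replace(record, foci=converted, space="MNI")


# ---------------------------------------------------------------------------
# Focus merging
# ---------------------------------------------------------------------------

def _single_linkage_clusters(pts: np.ndarray, radius_mm: float) -> np.ndarray:
    """Cluster ids (1-based) under single linkage at distance <= radius_mm."""
    if len(pts) == 1:
        return np.array([1])
    if np.all(pdist(pts) == 0):
        return np.ones(len(pts), dtype=int)
    z = linkage(pts, method="single")
    return fcluster(z, t=radius_mm, criterion="distance")


def merge_foci(foci, radius_mm: float = 10.0) -> np.ndarray:
    """Merge nearby foci: single-linkage clusters at Euclidean threshold
    ``radius_mm`` are replaced by their componentwise mean.

    Foci whose single-linkage distance exceeds the threshold remain separate
    coordinates. Input order does not matter: foci are processed (and the
    merged output returned) in lexicographic coordinate order.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    pts = np.asarray(foci, dtype=float)
    if pts.size == 0:
        raise ValueError("cannot merge an empty focus list")
    pts, _ = _as_points(pts)
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    pts = pts[order]
    ids = _single_linkage_clusters(pts, radius_mm)
    centroids = np.array([pts[ids == k].mean(axis=0) for k in np.unique(ids)])
    out_order = np.lexsort((centroids[:, 2], centroids[:, 1], centroids[:, 0]))
    return centroids[out_order]


# ---------------------------------------------------------------------------
# Atlas lookup
# ---------------------------------------------------------------------------

class AtlasVolume:
    """Integer label volume (NIfTI) with mm-coordinate parcel lookup.

    Lookup rounds the mm coordinate to the nearest voxel via the image
    affine. A coordinate that lands on background (label 0) is assigned to
    the nearest nonzero label within ``search_radius_mm``; a coordinate
    outside the volume's bounding box is unassignable.
    """

    def __init__(self, img):
        self.img = img
        self.data = np.asarray(img.dataobj).astype(int)
        self.affine = np.asarray(img.affine, dtype=float)
        self._inv = np.linalg.inv(self.affine)

    @classmethod
    def from_file(cls, path) -> "AtlasVolume":
        import nibabel as nib

        return cls(nib.load(str(path)))

    @property
    def labels(self) -> np.ndarray:
        labs = np.unique(self.data)
        return labs[labs != 0]

    def _voxel_index(self, xyz) -> np.ndarray:
        hom = np.append(np.asarray(xyz, dtype=float), 1.0)
        return np.round((self._inv @ hom)[:3]).astype(int)

    def label_at(self, xyz, search_radius_mm: float = 0.0):
        """Return ``(label, reason)``: label is ``None`` when unassignable,
        with reason ``"outside_volume"`` or ``"background"``."""
        ijk = self._voxel_index(xyz)
        shape = self.data.shape
        if np.any(ijk < 0) or np.any(ijk >= np.asarray(shape)):
            return None, "outside_volume"
        label = int(self.data[tuple(ijk)])
        if label != 0:
            return label, "direct"
        if search_radius_mm <= 0:
            return None, "background"
        zooms = np.linalg.norm(self.affine[:3, :3], axis=0)
        span = np.ceil(search_radius_mm / zooms).astype(int)
        best, best_d = None, np.inf
        for di in range(-span[0], span[0] + 1):
            for dj in range(-span[1], span[1] + 1):
                for dk in range(-span[2], span[2] + 1):
                    v = ijk + np.array([di, dj, dk])
                    if np.any(v < 0) or np.any(v >= np.asarray(shape)):
                        continue
                    lab = int(self.data[tuple(v)])
                    if lab == 0:
                        continue
                    center = (self.affine @ np.append(v, 1.0))[:3]
                    d = float(np.linalg.norm(center - np.asarray(xyz, dtype=float)))
                    if d <= search_radius_mm and d < best_d:
                        best, best_d = lab, d
        if best is None:
            return None, "background"
        return best, "nearest_nonzero"


# ---------------------------------------------------------------------------
# Region scores
# ---------------------------------------------------------------------------

def _focus_table(records: Sequence[ContrastRecord], merge_radius_mm: float) -> pd.DataFrame:
    rows = []
    for rec in records:
        if rec.space != "MNI":
            raise ValueError(
                f"record {rec.contrast_id!r} is in {rec.space} space; convert with "
                "to_mni() before scoring"
            )
        merged = merge_foci(rec.foci, radius_mm=merge_radius_mm)
        corr = code_correction(rec.correction)
        klass = code_contrast_class(rec.contrast_class)
        for x, y, z in merged:
            rows.append(
                {
                    "x": x,
                    "y": y,
                    "z": z,
                    "correction_code": np.nan if corr is EXCLUDED else corr,
                    "class_code": klass,
                    "contrast_id": rec.contrast_id,
                }
            )
    return pd.DataFrame(rows)


def region_scores(
    records: Iterable[ContrastRecord],
    atlas: AtlasVolume,
    mode: str = "median",
    merge_radius_mm: float = 10.0,
    search_radius_mm: float = 6.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score atlas regions from a corpus of MNI-space contrast records.

    Within each record, foci closer than ``merge_radius_mm`` are first merged
    (mean coordinate). Regions are then formed in one of two modes:

    * ``"median"`` (default): all foci are clustered spatially (single
      linkage at ``merge_radius_mm``); each cluster's componentwise median is
      assigned to an atlas parcel, and clusters mapping to the same parcel
      are collapsed.
    * ``"focus"``: every focus is assigned to a parcel individually and
      parcels accumulate their foci directly.

    Per region the componentwise median coordinate, the correction-level
    index (mean of coded corrections, unknown excluded), the
    semantics/control sensitivity index (mean of coded classes) and the
    number of distinct contributing contrasts are reported.

    Returns ``(regions, unassigned)``; foci that cannot be assigned to a
    parcel are reported in ``unassigned`` with a reason, never silently
    dropped.
    """
    records = list(records)
    foci = _focus_table(records, merge_radius_mm)
    if foci.empty:
        raise ValueError("no foci to score")
    if mode not in ("median", "focus"):
        raise ValueError(f"unknown mode {mode!r}")

    pts = foci[["x", "y", "z"]].to_numpy()
    unassigned_rows = []

    if mode == "focus":
        labels = np.zeros(len(foci), dtype=object)
        for i, p in enumerate(pts):
            lab, reason = atlas.label_at(p, search_radius_mm)
            labels[i] = lab
            if lab is None:
                unassigned_rows.append({**foci.iloc[i].to_dict(), "reason": reason})
        foci = foci.assign(atlas_label=labels)
        grouped = foci[foci["atlas_label"].notna()]
    else:
        cluster_ids = _single_linkage_clusters(pts, merge_radius_mm)
        labels = np.zeros(len(foci), dtype=object)
        for cid in np.unique(cluster_ids):
            sel = cluster_ids == cid
            med = np.median(pts[sel], axis=0)
            lab, reason = atlas.label_at(med, search_radius_mm)
            labels[sel] = lab
            if lab is None:
                for _, row in foci[sel].iterrows():
                    unassigned_rows.append({**row.to_dict(), "reason": reason})
        foci = foci.assign(atlas_label=labels)
        grouped = foci[foci["atlas_label"].notna()]

    regions = []
    for lab, grp in grouped.groupby("atlas_label", sort=True):
        med = grp[["x", "y", "z"]].median()
        corr = grp["correction_code"].dropna()
        regions.append(
            {
                "atlas_label": int(lab),
                "median_x": float(med["x"]),
                "median_y": float(med["y"]),
                "median_z": float(med["z"]),
                "correction_level_index": float(corr.mean()) if len(corr) else np.nan,
                "sensitivity_index": float(grp["class_code"].mean()),
                "n_contrasts": int(grp["contrast_id"].nunique()),
            }
        )
    regions_df = pd.DataFrame(
        regions,
        columns=[
            "atlas_label",
            "median_x",
            "median_y",
            "median_z",
            "correction_level_index",
            "sensitivity_index",
            "n_contrasts",
        ],
    )
    unassigned_df = pd.DataFrame(
        unassigned_rows,
        columns=["x", "y", "z", "correction_code", "class_code", "contrast_id", "reason"],
    )
    if len(unassigned_df):
        warnings.warn(
            f"{len(unassigned_df)} foci could not be assigned to an atlas parcel",
            stacklevel=2,
        )
    return regions_df, unassigned_df


# ---------------------------------------------------------------------------
# Tabular round trip
# ---------------------------------------------------------------------------

def records_to_table(records: Iterable[ContrastRecord]) -> pd.DataFrame:
    """Serialize records to a table; foci become ``"x,y,z;x,y,z"`` strings."""
    rows = [
        {
            "study_id": r.study_id,
            "contrast_id": r.contrast_id,
            "space": r.space,
            "correction": r.correction,
            "contrast_class": r.contrast_class,
            "foci": ";".join(",".join(f"{v:.4f}" for v in f) for f in r.foci),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["study_id", "contrast_id", "space", "correction", "contrast_class", "foci"],
    )


def table_to_records(table: pd.DataFrame) -> list[ContrastRecord]:
    """Inverse of :func:`records_to_table`."""
    records = []
    for _, row in table.iterrows():
        foci = tuple(
            tuple(float(v) for v in focus.split(",")) for focus in str(row["foci"]).split(";")
        )
        records.append(
            ContrastRecord(
                study_id=str(row["study_id"]),
                contrast_id=str(row["contrast_id"]),
                foci=foci,
                space=str(row["space"]),
                correction=str(row["correction"]),
                contrast_class=str(row["contrast_class"]),
            )
        )
    return records
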