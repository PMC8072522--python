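"""Subject-specific ROI atlases: lesion masking, extraction, hemispheric orientation.

The base atlas is an integer-labelled volume plus a manifest assigning each
ROI a name, a hemisphere (left/right/midline) and, for lateralized ROIs,
the id of its homologue in the opposite hemisphere.  For each stroke
subject the lesion is subtracted voxel-wise from every ROI, so the atlas
used for extraction is subject-specific; ROIs left with zero voxels are
flagged unavailable and propagate as missing values, never as zeros.

To pool patients with left- and right-sided lesions, matrices (or ROI
orderings) are reoriented by swapping homologous ROIs so that the lesioned
hemisphere always occupies a canonical side (right by default).  The swap
is an involution; healthy controls are never flipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

HEMISPHERES = ("left", "right", "midline")
CANONICAL_IPSILESIONAL_SIDE = "right"


@dataclass(frozen=True)
class RoiLabel:
    id: int
    name: str
    hemisphere: str
    homologue_id: int | None = None


@dataclass
class RoiAtlas:
    """Integer-labelled ROI volume with a hemisphere/homologue manifest."""

    label_volume: np.ndarray
    labels: list[RoiLabel]

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        ids = {lab.id for lab in self.labels}
        if len(ids) != len(self.labels):
            raise ValueError("duplicate ROI ids in manifest")
        present = set(np.unique(self.label_volume)) - {0}
        unknown = present - ids
        if unknown:
            raise ValueError(f"voxel labels {sorted(unknown)} absent from manifest")
        by_id = {lab.id: lab for lab in self.labels}
        for lab in self.labels:
            if lab.hemisphere not in HEMISPHERES:
                raise ValueError(f"ROI {lab.id}: bad hemisphere {lab.hemisphere!r}")
            if lab.hemisphere == "midline":
                if lab.homologue_id is not None:
                    raise ValueError(f"midline ROI {lab.id} must have no homologue")
                continue
            if lab.homologue_id is None:
                raise ValueError(f"lateralized ROI {lab.id} needs a homologue")
            twin = by_id.get(lab.homologue_id)
            if twin is None or twin.homologue_id != lab.id:
                raise ValueError(f"homologue mapping of ROI {lab.id} is not an involution")
            if twin.hemisphere == lab.hemisphere:
                raise ValueError(f"homologues {lab.id}/{twin.id} share a hemisphere")

    @property
    def roi_ids(self) -> list[int]:
        return [lab.id for lab in self.labels]

    @property
    def n_rois(self) -> int:
        return len(self.labels)

    def index_of(self, roi_id: int) -> int:
        return self.roi_ids.index(roi_id)

    def voxel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.label_volume, return_counts=True)
        table = dict(zip(ids.tolist(), counts.tolist()))
        return {lab.id: table.get(lab.id, 0) for lab in self.labels}


@dataclass
class SubjectAtlas:
    """A base atlas with one subject's lesion subtracted."""

    base: RoiAtlas
    lesion_side: str  # "left" | "right" | "none"
    masked_volume: np.ndarray
    original_counts: dict[int, int]
    surviving_counts: dict[int, int]
    lesion_mask: np.ndarray | None = None

    @property
    def availability(self) -> dict[int, bool]:
        return {rid: n > 0 for rid, n in self.surviving_counts.items()}

    @property
    def availability_array(self) -> np.ndarray:
        return np.array([self.surviving_counts[lab.id] > 0 for lab in self.base.labels])


def apply_lesion_mask(
    atlas: RoiAtlas,
    lesion: np.ndarray | None = None,
    lesion_side: str = "none",
    enabled: bool = True,
) -> SubjectAtlas:
    """Subtract lesion voxels from every ROI of the atlas.

    ``enabled=False`` keeps all voxels (the "unmasked" secondary analysis)
    while still recording the lesion side for orientation purposes.
    """
    original = atlas.voxel_counts()
    volume = atlas.label_volume.copy()
    if lesion is not None and enabled:
        lesion = np.asarray(lesion, dtype=bool)
        if lesion.shape != atlas.label_volume.shape:
            raise ValueError("lesion volume is not aligned with the atlas grid")
        volume[lesion] = 0
    surviving_raw = dict(zip(*[a.tolist() for a in np.unique(volume, return_counts=True)]))
    surviving = {lab.id: surviving_raw.get(lab.id, 0) for lab in atlas.labels}
    return SubjectAtlas(
        base=atlas,
        lesion_side=lesion_side,
        masked_volume=volume,
        original_counts=original,
        surviving_counts=surviving,
        lesion_mask=None if lesion is None else lesion,
    )


def extract_roi_series(
    bold: np.ndarray, subject_atlas: SubjectAtlas
) -> tuple[np.ndarray, np.ndarray]:
    """Mean time series per ROI over its surviving voxels.

    Returns a (n_frames, n_rois) matrix and a boolean availability array;
    unavailable ROIs get all-NaN columns.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 4:
        raise ValueError("expected 4D BOLD data")
    if bold.shape[:3] != subject_atlas.masked_volume.shape:
        raise ValueError("BOLD grid does not match atlas grid")
    n_frames = bold.shape[3]
    labels = subject_atlas.base.labels
    series = np.full((n_frames, len(labels)), np.nan)
    avail = subject_atlas.availability_array
    for pos, lab in enumerate(labels):
        if not avail[pos]:
            continue
        vox = subject_atlas.masked_volume == lab.id
        series[:, pos] = bold[vox].mean(axis=0)
    return series, avail


def homologue_positions(labels: list[RoiLabel]) -> np.ndarray:
    """Position permutation sending each lateralized ROI to its homologue."""
    index = {lab.id: pos for pos, lab in enumerate(labels)}
    perm = np.arange(len(labels))
    for pos, lab in enumerate(labels):
        if lab.homologue_id is not None:
            perm[pos] = index[lab.homologue_id]
    return perm


def orientation_permutation(
    labels: list[RoiLabel],
    lesion_side: str,
    canonical_side: str = CANONICAL_IPSILESIONAL_SIDE,
) -> np.ndarray:
    """Permutation putting the lesioned hemisphere on the canonical side.

    Identity when the lesion already sits on the canonical side; the
    homologue swap otherwise.  Applying it twice is the identity.
    """
    if lesion_side not in ("left", "right"):
        raise ValueError(
            f"orientation needs a lesion side of 'left' or 'right', got {lesion_side!r}"
        )
    if lesion_side == canonical_side:
        return np.arange(len(labels))
    return homologue_positions(labels)


def orient_matrix(z: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Apply an ROI permutation to the rows and columns of a square matrix."""
    z = np.asarray(z)
    if z.shape[0] != z.shape[1] or z.shape[0] != perm.shape[0]:
        raise ValueError("matrix/permutation size mismatch")
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.shape[0])
    return z[np.ix_(inv, inv)]


def orient_vector(v: np.ndarray, perm: np.ndarray) -> np.ndarray:
    v = np.asarray(v)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.shape[0])
    return v[inv]


def pair_compartment(
    labels: list[RoiLabel],
    pos_i: int,
    pos_j: int,
    canonical_side: str = CANONICAL_IPSILESIONAL_SIDE,
) -> str | None:
    """Compartment of an ROI pair in canonical (lesion-on-canonical-side) space.

    Returns "inter", "ipsi_intra" or "contra_intra"; None for pairs touching
    a midline ROI, which belong to no compartment.
    """
    hi, hj = labels[pos_i].hemisphere, labels[pos_j].hemisphere
    if "midline" in (hi, hj):
        return None
    if hi != hj:
        return "inter"
    return "ipsi_intra" if hi == canonical_side else "contra_intra"


# ---------------------------------------------------------------------------
# manifest / volume I/O


def labels_to_manifest(labels: list[RoiLabel]) -> list[dict]:
    return [
        {
            "id": lab.id,
            "name": lab.name,
            "hemisphere": lab.hemisphere,
            "homologue_id": lab.homologue_id,
        }
        for lab in labels
    ]


def manifest_to_labels(manifest: list[dict]) -> list[RoiLabel]:
    return [
        RoiLabel(
            id=int(e["id"]),
            name=str(e["name"]),
            hemisphere=str(e["hemisphere"]),
            homologue_id=None if e.get("homologue_id") is None else int(e["homologue_id"]),
        )
        for e in manifest
    ]


def save_manifest(labels: list[RoiLabel], path) -> None:
    with open(path, "w") as fh:
        json.dump(labels_to_manifest(labels), fh, indent=1)


def load_manifest(path) -> list[RoiLabel]:
    with open(path) as fh:
        return manifest_to_labels(json.load(fh))


def load_atlas(volume_path, manifest_path) -> RoiAtlas:
    import nibabel as nib

    img = nib.load(str(volume_path))
    volume = np.asarray(img.dataobj).astype(int)
    return RoiAtlas(label_volume=volume, labels=load_manifest(manifest_path))
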