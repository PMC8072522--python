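"""Synthetic stroke rehabilitation cohorts for exercising the full pipeline.

The study design being emulated: an ROI atlas of 106 lateralized regions
(92 cortical + 14 subcortical, no cerebellum), 7-minute resting-state runs
of 250 frames at TR = 1.7 s, 19 healthy controls scanned once and 30
stroke patients (18 sensorimotor-therapy arm, 12 motor-therapy arm)
scanned at baseline (T1), post-intervention (T2) and follow-up (T3), with
roughly one third of patient frames lost to motion scrubbing and lesions
confined to one hemisphere.

BOLD series are built from latent ROI signals drawn from a multivariate
normal whose correlation structure is a base template plus group-, arm-
and session-specific shifts (additive in Fisher-z space) on configured
connection sets; the latent signals are broadcast to the member voxels of
each ROI, mixed with voxel noise and tissue (WM/CSF) confound signals, and
overlaid with motion-spike artefacts aligned with the generated
realignment table.  Lesioned voxels carry noise only.  Everything is
deterministic given (seed, subject index, session index).

In addition to the volume-level generator, two light-weight generators
produce subject-level Fisher-z matrices and index tables directly; they
are used for the calibration experiments where thousands of subjects are
simulated and writing volumes would be pointless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from . import motion as motion_mod
from .atlas import RoiAtlas, RoiLabel
from .connectivity import fisher_z

SESSION_LABELS = ("T1", "T2", "T3")

#: realized sizes of the study's connection-of-interest sets, used as the
#: default planted counts: (class, compartment) -> n connections
DEFAULT_SET_COUNTS = {
    ("hypo", "inter"): 12,
    ("hyper", "inter"): 2,
    ("hypo", "ipsi_intra"): 8,
    ("hyper", "ipsi_intra"): 3,
    ("hypo", "contra_intra"): 4,
    ("hyper", "contra_intra"): 12,
}

_COMP_SHORT = {"inter": "inter", "ipsi_intra": "ipsi", "contra_intra": "contra"}


# ---------------------------------------------------------------------------
# toy atlas


def build_toy_atlas(
    n_rois: int = 106,
    grid_shape: tuple[int, int, int] = (30, 30, 30),
    subcortical_fraction: float = 14 / 106,
) -> tuple[RoiAtlas, dict[str, np.ndarray]]:
    """Block atlas on a small grid with mirrored left/right hemispheres.

    ROIs are 2x2x2 voxel blocks; position 2k holds the left member of pair
    k and position 2k+1 its right homologue (mirrored through the
    mid-sagittal plane).  An odd ``n_rois`` adds one midline ROI in the
    inter-hemispheric gap.  Returns the atlas plus WM / CSF / brain masks
    that do not overlap any ROI.
    """
    gx, gy, gz = grid_shape
    if n_rois < 2:
        raise ValueError("n_rois must be at least 2")
    n_pairs = n_rois // 2
    midline = n_rois % 2 == 1
    cx = gx // 2
    x_origins = list(range(1, cx - 2, 3))
    yz_origins = [
        (y, z) for y in range(1, gy - 2, 3) for z in range(2, gz - 2, 3)
    ]
    slots = [(x, y, z) for x in x_origins for (y, z) in yz_origins]
    if len(slots) < n_pairs + (1 if midline else 0):
        raise ValueError(
            f"grid {grid_shape} offers {len(slots)} block slots per hemisphere; "
            f"cannot place {n_pairs} ROI pairs"
        )
    volume = np.zeros(grid_shape, dtype=np.int16)
    labels: list[RoiLabel] = []
    n_cort_pairs = n_pairs - round(n_pairs * subcortical_fraction)
    for k in range(n_pairs):
        xo, yo, zo = slots[k]
        xr = gx - 2 - xo  # mirror of a 2-voxel block through x -> gx-1-x
        lid, rid = 2 * k + 1, 2 * k + 2
        volume[xo : xo + 2, yo : yo + 2, zo : zo + 2] = lid
        volume[xr : xr + 2, yo : yo + 2, zo : zo + 2] = rid
        tissue = "cortical" if k < n_cort_pairs else "subcortical"
        labels.append(RoiLabel(lid, f"{tissue}_{k:02d}_left", "left", rid))
        labels.append(RoiLabel(rid, f"{tissue}_{k:02d}_right", "right", lid))
    if midline:
        xo, yo, zo = cx - 1, *slots[n_pairs][1:]
        mid_id = n_rois
        volume[xo : xo + 2, yo : yo + 2, zo : zo + 2] = mid_id
        labels.append(RoiLabel(mid_id, "midline_00", "midline", None))
    roi_mask = volume > 0
    wm = np.zeros(grid_shape, dtype=bool)
    wm[cx - 1 : cx + 1, :, 2:] = True
    wm &= ~roi_mask
    csf = np.zeros(grid_shape, dtype=bool)
    csf[:, :, :2] = True
    csf &= ~roi_mask & ~wm
    brain = roi_mask | wm | csf
    return RoiAtlas(label_volume=volume, labels=labels), {
        "wm": wm,
        "csf": csf,
        "brain": brain,
    }


def default_connection_sets(
    n_rois: int,
    counts: dict[tuple[str, str], int] | None = None,
    hypo_shift: float = -0.5,
    hyper_shift: float = 0.5,
) -> tuple[list[tuple[int, int, float]], list[tuple[int, int, float]]]:
    """Planted aberrant-connection sets in canonical (lesion-right) space.

    Returns (hypo, hyper) lists of (pos_i, pos_j, z_shift).  ROIs are used
    at most once across all sets so set memberships stay disjoint.  The
    default counts are the study's realized set sizes.
    """
    counts = dict(DEFAULT_SET_COUNTS if counts is None else counts)
    n_pairs = n_rois // 2
    left = [2 * k for k in range(n_pairs)]  # canonical contralesional side
    right = [2 * k + 1 for k in range(n_pairs)]  # canonical ipsilesional side
    li, ri = iter(left), iter(right)

    def take(it, n):
        out = []
        for _ in range(n):
            try:
                out.append(next(it))
            except StopIteration:
                raise ValueError(
                    f"atlas with {n_rois} ROIs is too small for the requested sets"
                ) from None
        return out

    hypo: list[tuple[int, int, float]] = []
    hyper: list[tuple[int, int, float]] = []
    for (cls, comp), n in counts.items():
        shift = hypo_shift if cls == "hypo" else hyper_shift
        target = hypo if cls == "hypo" else hyper
        if comp == "inter":
            for a, b in zip(take(li, n), take(ri, n)):
                target.append((a, b, shift))
        elif comp == "ipsi_intra":
            pool = take(ri, 2 * n)
            for a, b in zip(pool[0::2], pool[1::2]):
                target.append((a, b, shift))
        elif comp == "contra_intra":
            pool = take(li, 2 * n)
            for a, b in zip(pool[0::2], pool[1::2]):
                target.append((a, b, shift))
        else:
            raise ValueError(f"unknown compartment {comp!r}")
    return hypo, hyper


# ---------------------------------------------------------------------------
# configuration


@dataclass
class BehaviourCoupling:
    """Linear coupling of a behavioural change score to a true index change."""

    index: str
    coef: float
    noise_sd: float
    baseline_mean: float
    baseline_sd: float


def _default_treatment_effects() -> dict:
    # arm -> session -> index -> additive Fisher-z shift relative to T1
    return {
        "sensorimotor": {"T2": {}, "T3": {}},
        "motor": {"T2": {"contra_hypo": 0.155, "contra_hyper": 0.144}, "T3": {}},
    }


def _default_behaviour_model() -> dict[str, BehaviourCoupling]:
    return {
        "arat": BehaviourCoupling("contra_hypo", 20.0, 2.0, 20.0, 10.0),
        "sulcs": BehaviourCoupling("contra_hyper", 10.0, 1.0, 4.0, 2.0),
    }


@dataclass
class CohortConfig:
    """Design constants of a synthetic cohort.

    Defaults mirror the emulated study: 19 controls, 18 + 12 stroke
    patients over two therapy arms, 106 ROIs, 250 frames at TR = 1.7 s,
    about 35% high-motion frames in patients, two-thirds right-sided
    lesions, aberrant-connection sets sized 12/2, 8/3 and 4/12 per
    compartment, and motor-arm pre-to-post index shifts of 0.155
    (contra_hypo) and 0.144 (contra_hyper) Fisher-z units.
    """

    n_controls: int = 19
    n_stroke_sensorimotor: int = 18
    n_stroke_motor: int = 12
    n_rois: int = 106
    n_frames: int = 250
    tr: float = 1.7
    n_sessions: int = 3
    grid_shape: tuple[int, int, int] = (30, 30, 30)
    lesion_side_probabilities: dict[str, float] = field(
        default_factory=lambda: {"right": 2 / 3, "left": 1 / 3}
    )
    base_z: float = 0.1
    hypo_connections: list[tuple[int, int, float]] | None = None
    hyper_connections: list[tuple[int, int, float]] | None = None
    treatment_effects: dict = field(default_factory=_default_treatment_effects)
    subject_shift_sd: float = 0.1
    spike_rate_patients: float = 0.35
    spike_rate_controls: float = 0.05
    #: Beta concentration of per-subject spike rates around the group rate;
    #: lower values give more between-subject motion heterogeneity (real
    #: cohorts show wide spreads of scrubbed-frame fractions)
    spike_rate_concentration: float = 15.0
    noise_sd: float = 1.0
    signal_amplitude: float = 10.0
    baseline_intensity: float = 1000.0
    bold_artefact_pct: float = 30.0
    tissue_noise_leak: float = 0.3
    behaviour_model: dict[str, BehaviourCoupling] = field(
        default_factory=_default_behaviour_model
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_stroke_sensorimotor", "n_stroke_motor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("n_rois", "n_frames", "n_sessions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_sessions > len(SESSION_LABELS):
            raise ValueError(f"n_sessions must be at most {len(SESSION_LABELS)}")
        probs = self.lesion_side_probabilities
        if set(probs) != {"left", "right"} or any(
            not 0 <= v <= 1 for v in probs.values()
        ) or abs(sum(probs.values()) - 1) > 1e-9:
            raise ValueError(
                "lesion_side_probabilities must give left/right probabilities summing to 1"
            )
        for name in ("spike_rate_patients", "spike_rate_controls"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.spike_rate_concentration <= 0:
            raise ValueError("spike_rate_concentration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.hypo_connections is None or self.hyper_connections is None:
            hypo, hyper = default_connection_sets(self.n_rois)
            if self.hypo_connections is None:
                self.hypo_connections = hypo
            if self.hyper_connections is None:
                self.hyper_connections = hyper
        for name in ("hypo_connections", "hyper_connections"):
            for (i, j, _dz) in getattr(self, name):
                if i == j or not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                    raise ValueError(
                        f"{name}: pair ({i}, {j}) must reference distinct valid ROI indices"
                    )

    @property
    def sessions(self) -> tuple[str, ...]:
        return SESSION_LABELS[: self.n_sessions]

    @property
    def n_stroke(self) -> int:
        return self.n_stroke_sensorimotor + self.n_stroke_motor

    def to_dict(self) -> dict:
        d = asdict(self)
        d["behaviour_model"] = {
            k: asdict(v) for k, v in self.behaviour_model.items()
        }
        d["grid_shape"] = list(self.grid_shape)
        # JSON-stable form: tuples become lists
        d["hypo_connections"] = [list(c) for c in self.hypo_connections]
        d["hyper_connections"] = [list(c) for c in self.hyper_connections]
        return d


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class SubjectTruth:
    subject_id: str
    group: str  # "control" | "stroke"
    arm: str  # "none" | "sensorimotor" | "motor"
    lesion_side: str  # "none" | "left" | "right"
    age: float
    sessions: list[str]
    spike_frames: dict[str, list[int]]
    index_shifts: dict[str, dict[str, float]]  # session -> index -> true shift vs T1
    behaviour_baseline: dict[str, float]
    fully_lesioned_rois: list[int]


@dataclass
class GroundTruth:
    """Manifest fully determining the expected recovery targets."""

    config: dict
    hypo_connections: list[tuple[int, int, float]]
    hyper_connections: list[tuple[int, int, float]]
    behaviour_couplings: dict[str, dict]
    subjects: list[SubjectTruth]

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "hypo_connections": [list(c) for c in self.hypo_connections],
            "hyper_connections": [list(c) for c in self.hyper_connections],
            "behaviour_couplings": self.behaviour_couplings,
            "subjects": [asdict(s) for s in self.subjects],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            config=d["config"],
            hypo_connections=[tuple(c) for c in d["hypo_connections"]],
            hyper_connections=[tuple(c) for c in d["hyper_connections"]],
            behaviour_couplings=d["behaviour_couplings"],
            subjects=[SubjectTruth(**s) for s in d["subjects"]],
        )


# ---------------------------------------------------------------------------
# correlation templates


def build_z_template(
    n_rois: int, base_z: float, entries: list[tuple[int, int, float]] = ()
) -> np.ndarray:
    """Symmetric Fisher-z template: constant background plus pair shifts."""
    z = np.full((n_rois, n_rois), float(base_z))
    np.fill_diagonal(z, 0.0)
    for i, j, dz in entries:
        z[i, j] += dz
        z[j, i] += dz
    return z


def template_correlation(z_template: np.ndarray) -> np.ndarray:
    """Correlation matrix tanh(Z) projected to the nearest valid one.

    Negative eigenvalues are clipped at a small floor and the diagonal is
    renormalized to 1, so heavily shifted templates stay usable.
    """
    r = np.tanh(z_template)
    np.fill_diagonal(r, 1.0)
    w, v = np.linalg.eigh(r)
    if w.min() < 1e-6:
        w = np.clip(w, 1e-6, None)
        r = (v * w) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
    return r


def _chol(r: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(r + 1e-8 * np.eye(len(r)))


def sample_roi_signals(
    z_template: np.ndarray, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_frames, n_rois) latent signals with the template's correlations."""
    L = _chol(template_correlation(z_template))
    return rng.standard_normal((n_frames, z_template.shape[0])) @ L.T


# ---------------------------------------------------------------------------
# realignment


def _realignment_with_spikes(
    n_frames: int, spike_rate: float, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[int]]:
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2 (FD is undefined otherwise)")
    if not 0 <= spike_rate <= 1:
        raise ValueError("spike_rate must lie in [0, 1]")
    steps = np.zeros((n_frames, 6))
    steps[1:, :3] = rng.normal(0, 0.008, size=(n_frames - 1, 3))
    steps[1:, 3:] = rng.normal(0, 5e-5, size=(n_frames - 1, 3))
    spike_frames = (1 + np.flatnonzero(rng.random(n_frames - 1) < spike_rate)).tolist()
    for t in spike_frames:
        axis = int(rng.integers(0, 3))
        steps[t, axis] += rng.uniform(0.7, 1.5) * (1 if rng.random() < 0.5 else -1)
    params = np.cumsum(steps, axis=0)
    df = pd.DataFrame(params, columns=motion_mod.REALIGNMENT_COLUMNS)
    return df, spike_frames


def generate_realignment(
    n_frames: int, spike_rate: float, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Realignment table: smooth low-amplitude drift plus step-like spikes.

    Spikes are persistent steps in one translation parameter sized so the
    frame-wise displacement of the spiked frame exceeds 0.5 mm; the
    expected fraction of frames exceeding the threshold is approximately
    ``spike_rate``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df, _ = _realignment_with_spikes(n_frames, spike_rate, rng)
    return df


# ---------------------------------------------------------------------------
# full cohort generation


def _native_pair(i: int, j: int, lesion_side: str, n_rois: int) -> tuple[int, int]:
    """Map a canonical-space pair to a subject's native hemispheres.

    Canonical space puts the lesion on the right; for a left-sided lesion
    the native pair is the homologue swap (even <-> odd positions within
    each lateralized pair; a trailing midline ROI maps to itself).
    """

    def swap(p: int) -> int:
        if p >= (n_rois // 2) * 2:  # midline ROI, odd n_rois
            return p
        return p + 1 if p % 2 == 0 else p - 1

    if lesion_side == "left":
        return swap(i), swap(j)
    return i, j


def _subject_session_template(
    config: CohortConfig,
    group: str,
    arm: str,
    lesion_side: str,
    session: str,
    subject_deviation: dict[str, float],
) -> tuple[np.ndarray, dict[str, float]]:
    """Z template for one subject-session plus the true per-index shifts."""
    entries: list[tuple[int, int, float]] = []
    shifts = {name: 0.0 for name in subject_deviation}
    if group == "stroke":
        planted = [(c, "hypo") for c in config.hypo_connections] + [
            (c, "hyper") for c in config.hyper_connections
        ]
        arm_effects = config.treatment_effects.get(arm, {}).get(session, {})
        post = session != "T1"
        if post:
            for name in shifts:
                shifts[name] = arm_effects.get(name, 0.0) + subject_deviation[name]
        for (i, j, dz), cls in planted:
            comp = _canonical_compartment(i, j, config.n_rois)
            name = f"{_COMP_SHORT[comp]}_{cls}"
            ni, nj = _native_pair(i, j, lesion_side, config.n_rois)
            entries.append((ni, nj, dz + shifts[name]))
    return build_z_template(config.n_rois, config.base_z, entries), shifts


def _canonical_compartment(i: int, j: int, n_rois: int) -> str:
    """Compartment of a canonical-space pair from position parity."""
    n_lat = (n_rois // 2) * 2
    if i >= n_lat or j >= n_lat:
        raise ValueError("planted connections may not touch midline ROIs")
    side_i = "contra" if i % 2 == 0 else "ipsi"  # even = left = contralesional
    side_j = "contra" if j % 2 == 0 else "ipsi"
    if side_i != side_j:
        return "inter"
    return "ipsi_intra" if side_i == "ipsi" else "contra_intra"


def _make_lesion(
    atlas: RoiAtlas, side: str, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """Lesion = one fully covered ROI block + half of a second, same side."""
    candidates = [lab for lab in atlas.labels if lab.hemisphere == side]
    picks = rng.choice(len(candidates), size=2, replace=False)
    full_roi = candidates[int(picks[0])]
    part_roi = candidates[int(picks[1])]
    lesion = np.zeros(atlas.label_volume.shape, dtype=bool)
    lesion |= atlas.label_volume == full_roi.id
    part_vox = np.argwhere(atlas.label_volume == part_roi.id)
    x_split = int(np.median(part_vox[:, 0]))
    for x, y, z in part_vox:
        if x <= x_split:
            lesion[x, y, z] = True
    return lesion, [full_roi.id]


def _save_nifti(data: np.ndarray, path: Path, dtype=np.float32) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine=np.diag([3.0, 3.0, 3.0, 1.0]))
    nib.save(img, str(path))


def generate_cohort(config: CohortConfig, output_dir) -> GroundTruth:
    """Write a complete synthetic cohort to ``output_dir``.

    Per subject and session: a 4D BOLD NIfTI and a realignment TSV; per
    stroke subject a binary lesion NIfTI; cohort-level: the atlas volume
    with its label manifest, WM/CSF/brain masks, a phenotype TSV and the
    ground-truth JSON manifest (which is also returned).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas, masks = build_toy_atlas(config.n_rois, config.grid_shape)
    _save_nifti(atlas.label_volume, out / "atlas.nii.gz", dtype=np.int16)
    atlas_mod.save_manifest(atlas.labels, out / "atlas_labels.json")
    for name in ("wm", "csf", "brain"):
        _save_nifti(masks[name].astype(np.uint8), out / f"{name}_mask.nii.gz", np.uint8)

    subjects: list[SubjectTruth] = []
    pheno_rows: list[dict] = []
    roster: list[tuple[str, str, str]] = []
    for k in range(config.n_controls):
        roster.append((f"ctrl-{k + 1:02d}", "control", "none"))
    for k in range(config.n_stroke_sensorimotor):
        roster.append((f"strk-{k + 1:02d}", "stroke", "sensorimotor"))
    for k in range(config.n_stroke_motor):
        roster.append(
            (f"strk-{config.n_stroke_sensorimotor + k + 1:02d}", "stroke", "motor")
        )

    index_names = [
        f"{_COMP_SHORT[comp]}_{cls}"
        for comp in _COMP_SHORT
        for cls in ("hypo", "hyper")
    ]
    brain = masks["brain"]
    wm, csf = masks["wm"], masks["csf"]

    for subj_idx, (sid, group, arm) in enumerate(roster):
        srng = np.random.default_rng([config.seed, subj_idx])
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        if group == "control":
            age = float(np.clip(srng.normal(65, 10), 30, 95))
            lesion_side = "none"
            lesion = None
            fully = []
            sessions = [SESSION_LABELS[0]]
            group_rate = config.spike_rate_controls
        else:
            mu, sd = (72, 12) if arm == "sensorimotor" else (61, 10)
            age = float(np.clip(srng.normal(mu, sd), 30, 95))
            p_right = config.lesion_side_probabilities["right"]
            lesion_side = "right" if srng.random() < p_right else "left"
            lesion, fully = _make_lesion(atlas, lesion_side, srng)
            _save_nifti(lesion.astype(np.uint8), sdir / "lesion.nii.gz", np.uint8)
            sessions = list(config.sessions)
            group_rate = config.spike_rate_patients
        kappa = config.spike_rate_concentration
        if 0 < group_rate < 1:
            spike_rate = float(
                srng.beta(kappa * group_rate, kappa * (1 - group_rate))
            )
        else:
            spike_rate = group_rate
        deviation = {
            name: float(srng.normal(0, config.subject_shift_sd))
            for name in index_names
        }
        behaviour_baseline = {
            score: float(srng.normal(c.baseline_mean, c.baseline_sd))
            for score, c in config.behaviour_model.items()
        }
        spike_frames: dict[str, list[int]] = {}
        index_shifts: dict[str, dict[str, float]] = {}
        for ses_idx, session in enumerate(sessions):
            rng = np.random.default_rng([config.seed, subj_idx, ses_idx])
            z_template, shifts = _subject_session_template(
                config, group, arm, lesion_side, session, deviation
            )
            index_shifts[session] = shifts
            latent = sample_roi_signals(z_template, config.n_frames, rng)
            wm_sig = rng.standard_normal(config.n_frames)
            csf_sig = rng.standard_normal(config.n_frames)
            realign, spikes = _realignment_with_spikes(
                config.n_frames, spike_rate, rng
            )
            spike_frames[session] = spikes

            signal = np.zeros(config.grid_shape + (config.n_frames,), dtype=np.float32)
            leak = config.tissue_noise_leak * (wm_sig + csf_sig)
            for pos, lab in enumerate(atlas.labels):
                vox = atlas.label_volume == lab.id
                if lesion is not None:
                    vox &= ~lesion
                if vox.any():
                    signal[vox] = (latent[:, pos] + leak).astype(np.float32)
            signal[wm] = wm_sig.astype(np.float32)
            signal[csf] = csf_sig.astype(np.float32)
            noise = rng.standard_normal(
                (int(brain.sum()), config.n_frames)
            ).astype(np.float32)
            data = np.zeros_like(signal)
            data[brain] = config.baseline_intensity + config.signal_amplitude * (
                signal[brain] + config.noise_sd * noise
            )
            if spikes:
                artefact = config.baseline_intensity * config.bold_artefact_pct / 100.0
                data[..., spikes] += artefact * brain[..., None].astype(np.float32)

            ses_dir = sdir / session
            ses_dir.mkdir(exist_ok=True)
            _save_nifti(data, ses_dir / "bold.nii.gz")
            realign.to_csv(ses_dir / "realignment.tsv", sep="\t", index=False)

            row = {
                "subject_id": sid,
                "group": group,
                "arm": arm,
                "lesion_side": lesion_side,
                "age": age,
                "session": session,
            }
            for score, c in config.behaviour_model.items():
                if group == "stroke":
                    true_change = shifts.get(c.index, 0.0) * c.coef
                    row[score] = float(
                        behaviour_baseline[score]
                        + true_change
                        + srng.normal(0, c.noise_sd)
                    )
                else:
                    row[score] = np.nan
            pheno_rows.append(row)
        subjects.append(
            SubjectTruth(
                subject_id=sid,
                group=group,
                arm=arm,
                lesion_side=lesion_side,
                age=age,
                sessions=sessions,
                spike_frames=spike_frames,
                index_shifts=index_shifts,
                behaviour_baseline=behaviour_baseline,
                fully_lesioned_rois=fully,
            )
        )

    pd.DataFrame(pheno_rows).to_csv(out / "phenotype.tsv", sep="\t", index=False)
    truth = GroundTruth(
        config=config.to_dict(),
        hypo_connections=[tuple(c) for c in config.hypo_connections],
        hyper_connections=[tuple(c) for c in config.hyper_connections],
        behaviour_couplings={
            k: asdict(v) for k, v in config.behaviour_model.items()
        },
        subjects=subjects,
    )
    truth.save(out / "ground_truth.json")
    return truth


# ---------------------------------------------------------------------------
# light-weight matrix- and index-level generators (calibration experiments)


def simulate_group_matrices(
    n_group0: int,
    n_group1: int,
    n_rois: int,
    n_frames: int,
    base_z: float = 0.1,
    group1_shifts: list[tuple[int, int, float]] = (),
    fd_group_difference: float = 0.176,
    rng: np.random.Generator | int = 0,
) -> dict[str, np.ndarray]:
    """Subject-level Fisher-z matrices for a two-group contrast experiment.

    Group 0 subjects follow the base template; group 1 subjects get the
    additional z shifts.  Each subject's matrix is the sample correlation
    of ``n_frames`` latent draws, Fisher z-transformed.  Mean FD values are
    drawn with a group offset mirroring the higher head motion of patients.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    templates = {
        0: build_z_template(n_rois, base_z),
        1: build_z_template(n_rois, base_z, group1_shifts),
    }
    chols = {g: _chol(template_correlation(t)) for g, t in templates.items()}
    groups = np.array([0] * n_group0 + [1] * n_group1)
    z_stack = np.empty((len(groups), n_rois, n_rois))
    for s, g in enumerate(groups):
        series = rng.standard_normal((n_frames, n_rois)) @ chols[g].T
        r = np.corrcoef(series, rowvar=False)
        z = fisher_z(r)
        np.fill_diagonal(z, np.nan)
        z_stack[s] = z
    mean_fd = rng.uniform(0.1, 0.3, size=len(groups)) + fd_group_difference * groups
    return {"z_stack": z_stack, "groups": groups, "mean_fd": mean_fd}


def simulate_index_cohort(
    n_sensorimotor: int = 18,
    n_motor: int = 12,
    arm_difference: float = -0.15,
    base_level: float = 0.3,
    session_effect: float = 0.05,
    subject_sd: float = 0.15,
    resid_sd: float = 0.1,
    age_change_coef: float = -0.001,
    fd_change_coef: float = -0.2,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Tidy per-subject index values at two sessions for one index.

    The true between-arm difference in pre-to-post change is
    ``arm_difference`` with the (sensorimotor - motor) sign convention.
    Age and mean FD covariates have small linear effects on the change and
    differ between arms, mirroring the emulated study's baseline
    imbalance.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    roster = [("sensorimotor", n_sensorimotor), ("motor", n_motor)]
    sid = 0
    for arm, n in roster:
        mu_age = 72 if arm == "sensorimotor" else 61
        for _ in range(n):
            sid += 1
            age = float(np.clip(rng.normal(mu_age, 11), 30, 95))
            fd = float(np.clip(rng.normal(0.25, 0.08), 0.05, None))
            intercept = base_level + rng.normal(0, subject_sd)
            change = (
                session_effect
                + (arm_difference if arm == "sensorimotor" else 0.0)
                + age_change_coef * (age - 65)
                + fd_change_coef * (fd - 0.25)
            )
            for session, offset in (("T1", 0.0), ("T2", change)):
                rows.append(
                    {
                        "subject_id": f"s{sid:03d}",
                        "session": session,
                        "value": intercept + offset + rng.normal(0, resid_sd),
                        "arm": arm,
                        "age": age,
                        "mean_fd": fd,
                    }
                )
    return pd.DataFrame(rows)
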