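"""End-to-end orchestration of the connectivity analysis.

Stages (each resumable from the previous stage's on-disk outputs):

1. preprocess -- motion summary + scrubbing mask, aCompCor confounds,
   lesion-masked ROI extraction, confound regression, band-pass.
2. connectivity -- Fisher-z ROI-to-ROI matrices over uncensored frames.
3. select -- baseline stroke-vs-control contrast with mean FD nuisance,
   seed-level FDR, hypo/hyper classification by compartment.
4. indices -- six connectivity indices per stroke subject per session.
5. infer -- mixed-model treatment effects per index and session contrast
   (age + session-averaged mean FD covariates, Bonferroni threshold) and
   Spearman partial correlations with behavioural change scores.

Input layout (as written by :func:`strokeconn.synthdata.generate_cohort`):
``atlas.nii.gz`` + ``atlas_labels.json``, ``wm/csf/brain_mask.nii.gz``,
``phenotype.tsv``, and per subject ``<sid>/lesion.nii.gz`` (stroke) plus
per session ``<sid>/<ses>/bold.nii.gz`` and ``realignment.tsv``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import connectivity as conn_mod
from . import denoise as den_mod
from . import indices as idx_mod
from . import inference as inf_mod
from . import motion as motion_mod
from . import selection as sel_mod

SESSIONS = ("T1", "T2", "T3")
PHENOTYPE_META = ["subject_id", "group", "arm", "lesion_side", "age", "session"]


@dataclass
class RunConfig:
    """Everything a run reads: paths, thresholds, toggles, seed.

    Defaults reproduce the primary analysis; ``lesion_masking`` and
    ``age_covariate`` toggles reproduce the secondary (robustness)
    analyses.
    """

    input_dir: str = "."
    output_dir: str = "derived"
    tr: float = 1.7
    fd_threshold: float = 0.5
    bold_threshold: float = 50.0
    band_low: float = 0.009
    band_high: float = 0.08
    fdr_alpha: float = 0.01
    fdr_mode: str = "any"
    bonferroni_alpha: float = 0.05
    n_time_contrasts: int = 3
    lesion_masking: bool = True
    age_covariate: bool = True
    fd_covariate: bool = True
    canonical_side: str = "right"
    flip_controls: bool = False
    compcor_k: int = 5
    censor_pad: int = 0
    rotations_degrees: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# helpers


def _load_volume(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).dataobj)


def _phenotype(cfg: RunConfig) -> pd.DataFrame:
    return pd.read_csv(Path(cfg.input_dir) / "phenotype.tsv", sep="\t")


def _subject_sessions(pheno: pd.DataFrame) -> list[tuple[str, str]]:
    return [(r.subject_id, r.session) for r in pheno.itertuples()]


def _roi_series_path(cfg: RunConfig, sid: str, ses: str) -> Path:
    return Path(cfg.output_dir) / "roiseries" / f"{sid}_{ses}.tsv"


def _motion_path(cfg: RunConfig, sid: str, ses: str) -> Path:
    return Path(cfg.output_dir) / "motion" / f"{sid}_{ses}.tsv"


def _matrix_path(cfg: RunConfig, sid: str, ses: str) -> Path:
    return Path(cfg.output_dir) / "matrices" / f"{sid}_{ses}.tsv"


def load_base_atlas(cfg: RunConfig) -> atlas_mod.RoiAtlas:
    root = Path(cfg.input_dir)
    return atlas_mod.load_atlas(root / "atlas.nii.gz", root / "atlas_labels.json")


# ---------------------------------------------------------------------------
# stage 1: preprocess


def stage_preprocess(cfg: RunConfig) -> None:
    """Motion metrics, scrubbing, aCompCor, lesion-masked ROI extraction,
    confound regression and band-pass for every subject-session."""
    root = Path(cfg.input_dir)
    atlas = load_base_atlas(cfg)
    wm = _load_volume(root / "wm_mask.nii.gz").astype(bool)
    csf = _load_volume(root / "csf_mask.nii.gz").astype(bool)
    brain = _load_volume(root / "brain_mask.nii.gz").astype(bool)
    pheno = _phenotype(cfg)
    for d in ("motion", "roiseries"):
        (Path(cfg.output_dir) / d).mkdir(parents=True, exist_ok=True)
    # one TR for the whole cohort, from any realignment/bold pair: stored in
    # the config implicitly through the band; TR is read per image header
    for row in pheno.itertuples():
        sid, ses = row.subject_id, row.session
        ses_dir = root / sid / ses
        bold = _load_volume(ses_dir / "bold.nii.gz").astype(float)
        realign = motion_mod.read_realignment(ses_dir / "realignment.tsv")
        summary = motion_mod.summarize_motion(
            realign,
            bold=bold,
            brain_mask=brain,
            fd_threshold=cfg.fd_threshold,
            bold_threshold=cfg.bold_threshold,
            degrees=cfg.rotations_degrees,
            pad=cfg.censor_pad,
        )
        motion_mod.write_motion_summary(summary, _motion_path(cfg, sid, ses))

        lesion_path = root / sid / "lesion.nii.gz"
        lesion = _load_volume(lesion_path).astype(bool) if lesion_path.exists() else None
        subject_atlas = atlas_mod.apply_lesion_mask(
            atlas,
            lesion,
            lesion_side=str(row.lesion_side),
            enabled=cfg.lesion_masking,
        )
        series, avail = atlas_mod.extract_roi_series(bold, subject_atlas)

        wm_pcs = den_mod.compcor_components(bold, wm, k=cfg.compcor_k)
        csf_pcs = den_mod.compcor_components(bold, csf, k=cfg.compcor_k)
        design = den_mod.build_confound_design(
            n_frames=series.shape[0],
            realignment=realign,
            censor_mask=summary.censor_mask,
            wm_components=wm_pcs,
            csf_components=csf_pcs,
        )
        clean = den_mod.denoise_series(
            series,
            design,
            tr=cfg.tr,
            low=cfg.band_low,
            high=cfg.band_high,
            censor_mask=summary.censor_mask,
        )
        out = pd.DataFrame(clean, columns=[f"roi_{rid}" for rid in atlas.roi_ids])
        out.to_csv(_roi_series_path(cfg, sid, ses), sep="\t", index=False)


# ---------------------------------------------------------------------------
# stage 2: connectivity matrices


def _load_matrix(cfg: RunConfig, sid: str, ses: str) -> conn_mod.ConnectivityMatrix:
    cm = conn_mod.read_matrix_tsv(_matrix_path(cfg, sid, ses))
    cm.subject_id, cm.session = sid, ses
    return cm


def stage_connectivity(cfg: RunConfig) -> None:
    pheno = _phenotype(cfg)
    (Path(cfg.output_dir) / "matrices").mkdir(parents=True, exist_ok=True)
    for row in pheno.itertuples():
        sid, ses = row.subject_id, row.session
        series = pd.read_csv(_roi_series_path(cfg, sid, ses), sep="\t")
        roi_ids = [int(c.removeprefix("roi_")) for c in series.columns]
        summary = motion_mod.read_motion_summary(_motion_path(cfg, sid, ses))
        cm = conn_mod.compute_matrix(
            series.to_numpy(dtype=float),
            censor_mask=summary.censor_mask,
            subject_id=sid,
            session=ses,
            roi_ids=roi_ids,
        )
        conn_mod.write_matrix_tsv(cm, _matrix_path(cfg, sid, ses))


# ---------------------------------------------------------------------------
# orientation helper


def _oriented_z(
    cfg: RunConfig,
    labels,
    cm: conn_mod.ConnectivityMatrix,
    lesion_side: str,
    group: str,
) -> np.ndarray:
    if group == "stroke":
        perm = atlas_mod.orientation_permutation(
            labels, lesion_side, canonical_side=cfg.canonical_side
        )
        return atlas_mod.orient_matrix(cm.z, perm)
    if cfg.flip_controls:
        raise ValueError("flip_controls has no defined lesion side for controls")
    return cm.z


# ---------------------------------------------------------------------------
# stage 3: selection


def stage_select(cfg: RunConfig) -> sel_mod.ConnectionSet:
    atlas = load_base_atlas(cfg)
    pheno = _phenotype(cfg)
    base = pheno[pheno["session"] == "T1"]
    z_list, group_list, fd_list = [], [], []
    for row in base.itertuples():
        sid = row.subject_id
        cm = _load_matrix(cfg, sid, "T1")
        z = _oriented_z(cfg, atlas.labels, cm, str(row.lesion_side), str(row.group))
        z_list.append(z)
        group_list.append(1 if row.group == "stroke" else 0)
        summary = motion_mod.read_motion_summary(_motion_path(cfg, sid, "T1"))
        fd_list.append(summary.mean_fd)
    conn, res = sel_mod.select_connections(
        np.stack(z_list),
        np.array(group_list),
        np.array(fd_list) if cfg.fd_covariate else None,
        atlas.labels,
        alpha=cfg.fdr_alpha,
        mode=cfg.fdr_mode,
        canonical_side=cfg.canonical_side,
    )
    table = conn.table.copy()
    ids = atlas.roi_ids
    table.insert(2, "roi_i_id", [ids[i] for i in table["roi_i"]])
    table.insert(3, "roi_j_id", [ids[j] for j in table["roi_j"]])
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "connections.tsv", sep="\t", index=False)
    return conn


def load_connection_set(cfg: RunConfig) -> sel_mod.ConnectionSet:
    """Read the connections-of-interest table (or a user-supplied one)."""
    table = pd.read_csv(Path(cfg.output_dir) / "connections.tsv", sep="\t")
    cols = ["roi_i", "roi_j", "cls", "compartment", "coefficient", "p", "p_fdr"]
    for c in cols:
        if c not in table.columns:
            table[c] = np.nan
    return sel_mod.ConnectionSet(table=table[cols])


# ---------------------------------------------------------------------------
# stage 4: indices


def stage_indices(cfg: RunConfig) -> pd.DataFrame:
    atlas = load_base_atlas(cfg)
    conn = load_connection_set(cfg)
    pheno = _phenotype(cfg)
    stroke = pheno[pheno["group"] == "stroke"]
    matrices = []
    for row in stroke.itertuples():
        cm = _load_matrix(cfg, row.subject_id, row.session)
        cm.z = _oriented_z(cfg, atlas.labels, cm, str(row.lesion_side), "stroke")
        matrices.append(cm)
    table = idx_mod.build_index_table(matrices, conn)
    table.to_csv(Path(cfg.output_dir) / "indices.tsv", sep="\t", index=False)
    return table


# ---------------------------------------------------------------------------
# stage 5: inference


def _session_mean_fd(cfg: RunConfig, sid: str, sessions: tuple[str, str]) -> float:
    vals = []
    for ses in sessions:
        path = _motion_path(cfg, sid, ses)
        if path.exists():
            vals.append(motion_mod.read_motion_summary(path).mean_fd)
    return float(np.mean(vals)) if vals else np.nan


def _index_inference_frame(
    cfg: RunConfig,
    index_table: pd.DataFrame,
    pheno: pd.DataFrame,
    index_name: str,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Tidy frame for one index/contrast with arm, age and averaged FD."""
    meta = (
        pheno[pheno["group"] == "stroke"]
        .groupby("subject_id")
        .first()[["arm", "age"]]
    )
    sub = index_table[
        (index_table["index_name"] == index_name)
        & (index_table["session"].isin(contrast))
    ].copy()
    sub = sub.merge(meta, left_on="subject_id", right_index=True, how="left")
    sub["mean_fd"] = [
        _session_mean_fd(cfg, sid, contrast) for sid in sub["subject_id"]
    ]
    return sub[["subject_id", "session", "value", "arm", "age", "mean_fd"]]


def stage_infer(cfg: RunConfig) -> dict:
    pheno = _phenotype(cfg)
    index_table = pd.read_csv(Path(cfg.output_dir) / "indices.tsv", sep="\t")
    contrasts = [("T1", "T2"), ("T1", "T3")]
    available_sessions = set(pheno["session"])
    contrasts = [c for c in contrasts if c[1] in available_sessions]
    thr = inf_mod.bonferroni_threshold(
        alpha=cfg.bonferroni_alpha,
        n_indices=len(idx_mod.INDEX_NAMES),
        n_time_contrasts=cfg.n_time_contrasts,
    )
    effects = []
    for contrast in contrasts:
        for name in idx_mod.INDEX_NAMES:
            tidy = _index_inference_frame(cfg, index_table, pheno, name, contrast)
            try:
                eff = inf_mod.treatment_effect(
                    tidy,
                    contrast=contrast,
                    use_age=cfg.age_covariate,
                    use_fd=cfg.fd_covariate,
                    index_name=name,
                )
                eff.significant = bool(eff.p < thr.raw)
            except ValueError:
                # index undefined for too many subjects (e.g. empty member
                # set): keep the row so every index is accounted for
                eff = inf_mod.TreatmentEffect(
                    index_name=name,
                    contrast=contrast,
                    estimate=np.nan,
                    se=np.nan,
                    p=np.nan,
                    n_sensorimotor=0,
                    n_motor=0,
                    covariates=[],
                    method="insufficient_data",
                    converged=False,
                    significant=None,
                )
            effects.append(eff)
    eff_table = pd.DataFrame(
        [
            {
                "index_name": e.index_name,
                "contrast": "->".join(e.contrast),
                "estimate": e.estimate,
                "se": e.se,
                "p": e.p,
                "significant": e.significant,
                "n_sensorimotor": e.n_sensorimotor,
                "n_motor": e.n_motor,
                "method": e.method,
                "converged": e.converged,
                "covariates": "+".join(e.covariates),
            }
            for e in effects
        ]
    )
    out = Path(cfg.output_dir)
    eff_table.to_csv(out / "treatment_effects.tsv", sep="\t", index=False)

    # brain-behaviour: index change vs behavioural change, T1 -> T2
    bb_rows = []
    score_cols = [c for c in pheno.columns if c not in PHENOTYPE_META]
    stroke = pheno[pheno["group"] == "stroke"]
    if ("T2" in available_sessions) and score_cols:
        deltas = idx_mod.change_scores(index_table, "T1", "T2")
        score_wide = stroke.pivot_table(
            index="subject_id", columns="session", values=score_cols, dropna=False
        )
        meta = stroke.groupby("subject_id").first()[["arm", "age"]]
        for name in idx_mod.INDEX_NAMES:
            dx = deltas[deltas["index_name"] == name].set_index("subject_id")["delta"]
            for score in score_cols:
                try:
                    dy = score_wide[(score, "T2")] - score_wide[(score, "T1")]
                except KeyError:
                    continue
                common = dx.index.intersection(dy.index)
                fd = pd.Series(
                    {sid: _session_mean_fd(cfg, sid, ("T1", "T2")) for sid in common}
                )
                cov = np.column_stack([meta.loc[common, "age"], fd.loc[common]])
                cov_names = ["age", "mean_fd"]
                if not cfg.age_covariate:
                    cov, cov_names = cov[:, 1:], ["mean_fd"]
                if not cfg.fd_covariate:
                    cov, cov_names = cov[:, :-1], cov_names[:-1]
                try:
                    res = inf_mod.partial_spearman(
                        dx.loc[common],
                        dy.loc[common],
                        cov if cov.shape[1] else None,
                        index_name=name,
                        behaviour=score,
                        covariate_names=cov_names,
                    )
                except ValueError:
                    continue
                bb_rows.append(
                    {
                        "index_name": name,
                        "behaviour": score,
                        "rho": res.rho,
                        "p": res.p,
                        "df": res.df,
                        "n": res.n,
                        "covariates": "+".join(res.covariates),
                    }
                )
    bb_table = pd.DataFrame(bb_rows)
    bb_table.to_csv(out / "brain_behaviour.tsv", sep="\t", index=False)
    return {
        "treatment_effects": eff_table,
        "brain_behaviour": bb_table,
        "bonferroni": thr,
    }


# ---------------------------------------------------------------------------
# full run


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write a run report; returns the key tables."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_preprocess(cfg)
    stage_connectivity(cfg)
    conn = stage_select(cfg)
    index_table = stage_indices(cfg)
    results = stage_infer(cfg)
    import strokeconn

    report = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "package_version": strokeconn.__version__,
        "n_subject_sessions": len(_phenotype(cfg)),
        "n_selected_connections": len(conn),
        "connection_counts": {
            f"{cls}/{comp}": n for (cls, comp), n in conn.counts().items()
        },
        "bonferroni_threshold": results["bonferroni"].raw,
        "bonferroni_threshold_rounded": results["bonferroni"].rounded,
        "lesion_masking": cfg.lesion_masking,
        "age_covariate": cfg.age_covariate,
        "fd_covariate": cfg.fd_covariate,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    results.update({"connections": conn, "index_table": index_table, "report": report})
    return results
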