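"""Hemispheric connectivity indices.

Six indices per stroke subject per session: the mean Fisher-z value over
the selected hypo- or hyper-connected connections of each compartment
(interhemispheric, ipsilesional intrahemispheric, contralesional
intrahemispheric).  Connections with an unavailable (fully lesioned) ROI
are skipped; an index with no available member connections is missing, not
zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .selection import ConnectionSet

INDEX_NAMES = (
    "inter_hypo",
    "inter_hyper",
    "ipsi_hypo",
    "ipsi_hyper",
    "contra_hypo",
    "contra_hyper",
)

_COMPARTMENT_SHORT = {"inter": "inter", "ipsi_intra": "ipsi", "contra_intra": "contra"}


def index_name(cls: str, compartment: str) -> str:
    return f"{_COMPARTMENT_SHORT[compartment]}_{cls}"


def index_members(connections: ConnectionSet) -> dict[str, list[tuple[int, int]]]:
    """Member connection list (ROI position pairs) per index name."""
    members: dict[str, list[tuple[int, int]]] = {name: [] for name in INDEX_NAMES}
    for row in connections.table.itertuples():
        members[index_name(row.cls, row.compartment)].append(
            (int(row.roi_i), int(row.roi_j))
        )
    return members


def compute_indices(
    matrix: ConnectivityMatrix | np.ndarray,
    connections: ConnectionSet,
) -> pd.DataFrame:
    """Six index values from one (canonically oriented) connectivity matrix.

    Returns a frame with columns index_name, value, n_connections_used.
    """
    z = matrix.z if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    members = index_members(connections)
    rows = []
    for name in INDEX_NAMES:
        vals = [z[i, j] for i, j in members[name]]
        vals = [v for v in vals if np.isfinite(v)]
        rows.append(
            {
                "index_name": name,
                "value": float(np.mean(vals)) if vals else np.nan,
                "n_connections_used": len(vals),
            }
        )
    return pd.DataFrame(rows)


def build_index_table(
    matrices: list[ConnectivityMatrix],
    connections: ConnectionSet,
) -> pd.DataFrame:
    """Long IndexTable over subject-sessions: one row per (subject, session, index)."""
    frames = []
    for cm in matrices:
        df = compute_indices(cm, connections)
        df.insert(0, "session", cm.session)
        df.insert(0, "subject_id", cm.subject_id)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["subject_id", "session", "index_name", "value", "n_connections_used"]
        )
    return pd.concat(frames, ignore_index=True)


def change_scores(
    index_table: pd.DataFrame,
    from_session: str = "T1",
    to_session: str = "T2",
) -> pd.DataFrame:
    """Per-subject per-index delta = value(to_session) - value(from_session).

    Subjects missing either session (or with a missing index value) get a
    missing delta and are excluded downstream.
    """
    wide = index_table.pivot_table(
        index=["subject_id", "index_name"],
        columns="session",
        values="value",
        dropna=False,
    )
    for ses in (from_session, to_session):
        if ses not in wide.columns:
            wide[ses] = np.nan
    out = wide.reset_index()[["subject_id", "index_name"]].copy()
    out["delta"] = (wide[to_session] - wide[from_session]).to_numpy()
    out["from_session"] = from_session
    out["to_session"] = to_session
    return out
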