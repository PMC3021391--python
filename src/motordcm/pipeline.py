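"""Batch plumbing: invert many (session, model) pairs and collect results.

Results are serialised one JSON file per (session, model) so long runs are
resumable; the evidence table and parameter panels are assembled from the
in-memory or on-disk store.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SessionData
from .group_bms import EvidenceTable
from .inversion import (
    InversionOptions,
    ModelEvidence,
    Posterior,
    connectivity_names,
    invert,
    posterior_correlation,
)
from .model_space import ModelSpec, get_model
from .reliability import ParamPanel

__all__ = [
    "schedule",
    "invert_sessions",
    "evidence_table",
    "panel_from_store",
    "posterior_corr_stack",
    "result_to_dict",
    "result_from_dict",
]


def schedule(sessions: list[SessionData], models: list[ModelSpec]) -> list[tuple[str, str]]:
    """All (session_id, model_id) jobs, in deterministic order."""
    return [(s.session_id, m.model_id) for s in sessions for m in models]


def result_to_dict(
    session: SessionData, model: ModelSpec, post: Posterior, ev: ModelEvidence
) -> dict:
    return {
        "session_id": session.session_id,
        "subject_id": session.subject_id,
        "group": session.group,
        "session": session.session,
        "model_id": model.model_id,
        "F": ev.F,
        "accuracy": ev.accuracy,
        "complexity": ev.complexity,
        "converged": bool(post.converged),
        "n_iter": int(post.n_iter),
        "names": list(post.names),
        "Ep": post.Ep.tolist(),
        "Cp": post.Cp.tolist(),
        "log_precision": post.log_precision.tolist(),
    }


def result_from_dict(d: dict) -> dict:
    d = dict(d)
    d["Ep"] = np.asarray(d["Ep"])
    d["Cp"] = np.asarray(d["Cp"])
    d["log_precision"] = np.asarray(d["log_precision"])
    return d


def invert_sessions(
    sessions: list[SessionData],
    models: list[ModelSpec] | list[str],
    opts: InversionOptions = InversionOptions(),
    out_dir=None,
    progress: bool = False,
) -> list[dict]:
    """Invert every model on every session; resumable via ``out_dir``.

    Returns one record per (session, model) with the free-energy
    decomposition and the posterior (see :func:`result_to_dict`).
    """
    models = [get_model(m) if isinstance(m, str) else m for m in models]
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    results = []
    n_jobs = len(sessions) * len(models)
    done = 0
    for s in sessions:
        for m in models:
            done += 1
            path = out / f"{s.session_id}__{m.model_id}.json" if out is not None else None
            if path is not None and path.exists():
                results.append(result_from_dict(json.loads(path.read_text())))
                continue
            post, ev = invert(m, s.timeseries, s.design, opts=opts)
            rec = result_to_dict(s, m, post, ev)
            if path is not None:
                path.write_text(json.dumps(rec))
            results.append(result_from_dict(rec))
            if progress:
                print(f"[{done}/{n_jobs}] {s.session_id} {m.model_id} F={ev.F:.2f}")
    return results


def evidence_table(results: list[dict]) -> EvidenceTable:
    """Assemble the sessions x models free-energy table from records."""
    meta_cols = ["session_id", "subject_id", "group", "session"]
    rows = {}
    meta = {}
    for r in results:
        sid = r["session_id"]
        meta[sid] = {c: r[c] for c in meta_cols}
        rows.setdefault(sid, {})[r["model_id"]] = r["F"]
    session_ids = list(meta)
    F = pd.DataFrame([rows[sid] for sid in session_ids], index=range(len(session_ids)))
    if F.isna().any().any():
        missing = [
            (sid, m)
            for sid, row in zip(session_ids, F.to_numpy())
            for m, v in zip(F.columns, row)
            if np.isnan(v)
        ]
        raise ValueError(f"incomplete evidence table; missing {missing[:5]}...")
    meta_df = pd.DataFrame([meta[sid] for sid in session_ids], index=range(len(session_ids)))
    return EvidenceTable(meta=meta_df, F=F)


def panel_from_store(results: list[dict], model_id: str) -> ParamPanel:
    """Connectivity posterior means as a long-format reliability panel."""
    recs = []
    for r in results:
        if r["model_id"] != model_id:
            continue
        keep = [i for i, n in enumerate(r["names"]) if not n.startswith("hemo.")]
        for i in keep:
            recs.append(
                {
                    "subject": r["subject_id"],
                    "group": r["group"],
                    "session": r["session"],
                    "parameter": r["names"][i],
                    "value": float(r["Ep"][i]),
                }
            )
    if not recs:
        raise ValueError(f"no results for model {model_id}")
    return ParamPanel(pd.DataFrame.from_records(recs))


def posterior_corr_stack(
    results: list[dict],
    model_id: str,
    group: str | None = None,
    session: str | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Stack of per-session posterior correlation matrices (A/B/C block)."""
    mats = []
    names = None
    for r in results:
        if r["model_id"] != model_id:
            continue
        if group is not None and r["group"] != group:
            continue
        if session is not None and r["session"] != session:
            continue
        corr = posterior_correlation(r["Cp"], r["names"])
        mats.append(corr)
        if names is None:
            names = [n for n in r["names"] if not n.startswith("hemo.")]
    if not mats:
        raise ValueError("no matching results")
    return np.asarray(mats), names
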