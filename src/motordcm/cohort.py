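"""Synthetic study-shaped cohorts with known ground truth.

Emulates the structure of the action-selection study: 28 young adults
(one session), 15 older controls (two sessions, randomly labelled A/B) and
16 Parkinson's-disease patients (one session on dopaminergic medication,
one off, order permuted within blocks of six subjects) — 90 sessions in
all.  Controls and patients-on generate data from model E2 (contextual
modulation of the PFC <-> preSMA couplings); patients-off from model E1
(modulation of PFC <-> PM), mirroring the medial-to-lateral shift the
disease model predicts.

Each subject draws connectivity parameters around group means with a
between-subject SD, each session adds a smaller within-subject jitter, and
observation noise is i.i.d. Gaussian per region scaled to a target
time-series SNR.  Everything is reproducible from the master seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .generative import (
    ConnectivityParams,
    HemoParams,
    RegionTimeSeries,
    SimulationError,
    StimulusDesign,
    build_design,
    simulate_bold,
)
from .model_space import REGIONS, ModelSpec, get_model

__all__ = [
    "GroupSpec",
    "CohortConfig",
    "SessionData",
    "CohortTruth",
    "default_study_config",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

_IDX = {r: i for i, r in enumerate(REGIONS)}

# Group-mean intrinsic couplings (Hz) for the bidirectional skeleton: a
# rostro-caudal hierarchy with strong feed-forward and weak feedback
# couplings, heterogeneous across connections.  Directed (source, target).
DEFAULT_A_MEANS: dict[tuple[str, str], float] = {
    ("PFC", "PM"): 0.45,
    ("PFC", "preSMA"): 0.45,
    ("PM", "preSMA"): 0.35,
    ("preSMA", "PM"): 0.05,
    ("PM", "M1"): 0.20,
    ("preSMA", "M1"): 0.20,
    ("PM", "PFC"): 0.05,
    ("preSMA", "PFC"): 0.05,
    ("M1", "PM"): 0.05,
    ("M1", "preSMA"): 0.05,
}

#: Group-mean bilinear modulations (Hz) on the edges a truth model modulates:
#: rostro-caudal ("forward") edges and their reciprocals.
DEFAULT_B_FORWARD = 0.06
DEFAULT_B_BACKWARD = 0.05
_FORWARD_EDGES = {
    ("PFC", "PM"),
    ("PFC", "preSMA"),
    ("preSMA", "PM"),
    ("PM", "M1"),
    ("preSMA", "M1"),
}

DEFAULT_C_U1 = 0.10  # driving input to PFC, older subjects
DEFAULT_C_U1_YOUNG = 0.09
DEFAULT_C_U2 = 0.05  # contextual driving input (model sets B/D/F only)


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_subjects: int
    session_labels: tuple[str, ...]  # one per session
    truth_models: tuple[str, ...]  # one per session label
    randomize_session_order: bool = False
    permute_block: int | None = None  # permute order within blocks of this size


@dataclass
class CohortConfig:
    groups: tuple[GroupSpec, ...]
    a_means: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_A_MEANS)
    )
    b_forward: float = DEFAULT_B_FORWARD
    b_backward: float = DEFAULT_B_BACKWARD
    c_u1: dict[str, float] = field(default_factory=dict)  # per group label
    c_u2: float = DEFAULT_C_U2
    between_subject_sd: float = 0.05
    session_jitter_sd: float = 0.02
    snr: float = 2.0
    noise_ar1: float = 0.0
    n_per_condition: int = 40
    soa: float = 2.5
    tr: float = 2.0
    n_volumes: int = 150
    duration: float = 1.0
    sigma_self: float = 0.5
    hemo: HemoParams = field(default_factory=HemoParams)
    dt_micro: float = 0.1
    center_u2: bool = False
    u2_span: str = "trial"
    stability_margin: float = 0.05  # require max Re eigenvalue < -margin
    master_seed: int = 0

    def n_sessions(self) -> int:
        return sum(g.n_subjects * len(g.session_labels) for g in self.groups)


def default_study_config(seed: int = 0) -> CohortConfig:
    """The study roster: 28 young, 15 older controls, 16 PD; 90 sessions."""
    groups = (
        GroupSpec("young", 28, ("A",), ("E2",)),
        GroupSpec("OC", 15, ("A", "B"), ("E2", "E2"), randomize_session_order=True),
        GroupSpec("PD", 16, ("on", "off"), ("E2", "E1"), permute_block=6),
    )
    return CohortConfig(
        groups=groups,
        c_u1={"young": DEFAULT_C_U1_YOUNG},
        master_seed=seed,
    )


@dataclass
class SessionData:
    session_id: str
    subject_id: str
    group: str
    session: str
    order: int  # acquisition order within subject (0-based)
    design: StimulusDesign
    timeseries: RegionTimeSeries
    truth_model: str


@dataclass
class CohortTruth:
    """Per-session ground truth: generating model and true parameters."""

    records: list[dict]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def for_session(self, session_id: str) -> dict:
        for rec in self.records:
            if rec["session_id"] == session_id:
                return rec
        raise KeyError(session_id)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.records, indent=1))

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        return cls(records=json.loads(Path(path).read_text()))


def _param_means(model: ModelSpec, group: str, config: CohortConfig) -> dict[str, float]:
    """Group-mean value for every free connectivity entry of ``model``."""
    means: dict[str, float] = {}
    for i, j in zip(*np.nonzero(model.a_mask)):
        src, tgt = REGIONS[j], REGIONS[i]
        means[f"A.{src}->{tgt}"] = config.a_means.get((src, tgt), 0.05)
    for i, j in zip(*np.nonzero(model.b_mask)):
        src, tgt = REGIONS[j], REGIONS[i]
        fwd = (src, tgt) in _FORWARD_EDGES
        means[f"B.{src}->{tgt}"] = config.b_forward if fwd else config.b_backward
    for i, j in zip(*np.nonzero(model.c_mask)):
        base = config.c_u1.get(group, DEFAULT_C_U1) if j == 0 else config.c_u2
        means[f"C.{REGIONS[i]}.u{j + 1}"] = base
    return means


def _params_from_dict(model: ModelSpec, values: dict[str, float], sigma_self: float) -> ConnectivityParams:
    A = np.zeros((4, 4))
    B = np.zeros((4, 4))
    C = np.zeros((4, 2))
    for name, v in values.items():
        kind, rest = name.split(".", 1)
        if kind in ("A", "B"):
            src, tgt = rest.split("->")
            (A if kind == "A" else B)[_IDX[tgt], _IDX[src]] = v
        else:
            region, u = rest.split(".")
            C[_IDX[region], int(u[1]) - 1] = v
    return ConnectivityParams(A=A, B=B, C=C, sigma_self=sigma_self)


def _stable(params: ConnectivityParams, margin: float) -> bool:
    """Resting state decays with the configured margin; the transiently
    modulated (u2 = 1) configuration must merely be non-expanding."""
    if float(np.linalg.eigvals(params.effective_A).real.max()) >= -margin:
        return False
    modulated = params.effective_A + params.B
    return float(np.linalg.eigvals(modulated).real.max()) < 0.0


def _draw_subject(
    truth_models: list[ModelSpec],
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> dict[str, float]:
    """Subject-level parameter draw on the union support of the truth models."""
    union_means: dict[str, float] = {}
    for m in truth_models:
        union_means.update(_param_means(m, group, config))
    for attempt in range(max_retries):
        values = {
            k: v + rng.normal(0.0, config.between_subject_sd)
            for k, v in union_means.items()
        }
        ok = True
        for m in truth_models:
            sess_vals = {k: v for k, v in values.items() if k in _param_means(m, group, config)}
            p = _params_from_dict(m, sess_vals, config.sigma_self)
            if not _stable(p, config.stability_margin):
                ok = False
                break
        if ok:
            if attempt > 0:
                warnings.warn(
                    f"redrew unstable subject parameters ({attempt} retries)",
                    RuntimeWarning,
                )
            return values
    raise RuntimeError("could not draw stable subject parameters")


def _session_params(
    model: ModelSpec,
    group: str,
    subject_values: dict[str, float],
    config: CohortConfig,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> tuple[ConnectivityParams, dict[str, float]]:
    names = list(_param_means(model, group, config))
    for attempt in range(max_retries):
        vals = {
            k: subject_values[k] + rng.normal(0.0, config.session_jitter_sd)
            for k in names
        }
        p = _params_from_dict(model, vals, config.sigma_self)
        if _stable(p, config.stability_margin):
            return p, vals
    raise RuntimeError("could not draw stable session parameters")


def generate_cohort(config: CohortConfig) -> tuple[list[SessionData], CohortTruth]:
    """Simulate every session of the configured cohort.

    Per-region noise is scaled so that each region's noiseless signal SD
    over the session divided by the noise SD equals the configured SNR.
    """
    root = np.random.SeedSequence(config.master_seed)
    sessions: list[SessionData] = []
    records: list[dict] = []
    group_seeds = root.spawn(len(config.groups))
    for gspec, gseed in zip(config.groups, group_seeds):
        truth_models = [get_model(mid) for mid in gspec.truth_models]
        n_sess = len(gspec.session_labels)
        label_rng = np.random.default_rng(gseed.spawn(1)[0])
        # acquisition order of the labelled sessions, per subject
        orders = []
        for sub in range(gspec.n_subjects):
            orders.append(np.arange(n_sess))
        if gspec.randomize_session_order and n_sess > 1:
            orders = [label_rng.permutation(n_sess) for _ in range(gspec.n_subjects)]
        elif gspec.permute_block and n_sess > 1:
            orders = []
            for start in range(0, gspec.n_subjects, gspec.permute_block):
                block = min(gspec.permute_block, gspec.n_subjects - start)
                half = [np.array([0, 1]), np.array([1, 0])] * ((block + 1) // 2)
                perm = label_rng.permutation(block)
                orders.extend(half[i] for i in perm)
        subj_seeds = gseed.spawn(gspec.n_subjects)
        for s_ix in range(gspec.n_subjects):
            subject_id = f"{gspec.label}{s_ix + 1:02d}"
            sseq = subj_seeds[s_ix]
            subj_rng = np.random.default_rng(sseq.spawn(1)[0])
            subj_values = _draw_subject(truth_models, gspec.label, config, subj_rng)
            sess_seeds = sseq.spawn(n_sess)
            for k, (label, mid) in enumerate(zip(gspec.session_labels, gspec.truth_models)):
                model = get_model(mid)
                sess_seq = sess_seeds[k]
                design_seed, jitter_seed, noise_seed = sess_seq.spawn(3)
                jrng = np.random.default_rng(jitter_seed)
                design = build_design(
                    config.n_per_condition,
                    config.soa,
                    seed=design_seed,
                    duration=config.duration,
                    tr=config.tr,
                    n_volumes=config.n_volumes,
                )
                # eigenvalue pre-checks do not rule out divergence of the
                # switched (u2 on/off) system, so redraw on simulation failure
                clean = None
                for attempt in range(50):
                    params, vals = _session_params(
                        model, gspec.label, subj_values, config, jrng)
                    try:
                        clean = simulate_bold(
                            model, params, design, noise_sd=0.0,
                            hemo=config.hemo, dt_micro=config.dt_micro,
                            center_u2=config.center_u2, u2_span=config.u2_span,
                        )
                        break
                    except SimulationError:
                        continue
                if clean is None:
                    raise RuntimeError(
                        f"could not simulate a stable session for {subject_id}")
                if attempt > 0:
                    warnings.warn(
                        f"redrew diverging session parameters for {subject_id} "
                        f"({attempt} retries)", RuntimeWarning)
                sd_r = clean.y.std(axis=0)
                noise_sd = sd_r / config.snr if config.snr > 0 else np.zeros(4)
                nrng = np.random.default_rng(noise_seed)
                eps = nrng.normal(0.0, 1.0, clean.y.shape)
                if config.noise_ar1 > 0:
                    phi = config.noise_ar1
                    for t in range(1, eps.shape[0]):
                        eps[t] = phi * eps[t - 1] + np.sqrt(1 - phi**2) * eps[t]
                y = clean.y + eps * noise_sd
                ts = RegionTimeSeries(y=y, tr=config.tr)
                session_id = f"{subject_id}_{label}"
                order = int(orders[s_ix][k])
                sessions.append(
                    SessionData(
                        session_id=session_id,
                        subject_id=subject_id,
                        group=gspec.label,
                        session=label,
                        order=order,
                        design=design,
                        timeseries=ts,
                        truth_model=mid,
                    )
                )
                records.append(
                    {
                        "session_id": session_id,
                        "subject_id": subject_id,
                        "group": gspec.label,
                        "session": label,
                        "order": order,
                        "truth_model": mid,
                        "params": {k2: float(v2) for k2, v2 in vals.items()},
                        "noise_sd": noise_sd.tolist(),
                    }
                )
    return sessions, CohortTruth(records=records)


# --------------------------------------------------------------------------
# directory round-trip
# --------------------------------------------------------------------------


def write_cohort(sessions: list[SessionData], truth: CohortTruth | None, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "regions": list(REGIONS),
        "sessions": [
            {
                "session_id": s.session_id,
                "subject_id": s.subject_id,
                "group": s.group,
                "session": s.session,
                "order": s.order,
                "truth_model": s.truth_model,
                "tr": s.design.tr,
                "n_volumes": s.design.n_volumes,
                "soa": s.design.soa,
            }
            for s in sessions
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for s in sessions:
        s.timeseries.to_frame().to_csv(out / f"{s.session_id}_bold.tsv", sep="\t",
                                       index=False, float_format="%.15g")
        s.design.to_frame().to_csv(out / f"{s.session_id}_design.csv", index=False,
                                   float_format="%.15g")
    if truth is not None:
        truth.to_json(out / "truth.json")


def read_cohort(cohort_dir) -> tuple[list[SessionData], CohortTruth | None]:
    root = Path(cohort_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    sessions = []
    for rec in manifest["sessions"]:
        sid = rec["session_id"]
        bold = pd.read_csv(root / f"{sid}_bold.tsv", sep="\t")
        dsg = pd.read_csv(root / f"{sid}_design.csv", keep_default_na=False)
        design = StimulusDesign(
            onsets=dsg["onset_s"].to_numpy(),
            durations=dsg["duration_s"].to_numpy(),
            conditions=tuple(dsg["condition"]),
            soa=rec["soa"],
            tr=rec["tr"],
            n_volumes=rec["n_volumes"],
        )
        ts = RegionTimeSeries(
            y=bold[list(manifest["regions"])].to_numpy(), tr=rec["tr"],
            regions=tuple(manifest["regions"]),
        )
        sessions.append(
            SessionData(
                session_id=sid,
                subject_id=rec["subject_id"],
                group=rec["group"],
                session=rec["session"],
                order=rec["order"],
                design=design,
                timeseries=ts,
                truth_model=rec["truth_model"],
            )
        )
    truth_path = root / "truth.json"
    truth = CohortTruth.from_json(truth_path) if truth_path.exists() else None
    return sessions, truth
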