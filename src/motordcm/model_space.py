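"""Model space for effective connectivity in a 4-region frontal motor network.

The network comprises dorsolateral prefrontal cortex (PFC), lateral premotor
cortex (PM), pre-supplementary motor area (preSMA) and primary motor cortex
(M1).  Forty-eight bilinear dynamic causal models are enumerated as the cross
product of six intrinsic-connectivity structures (letters A-F) with eight
contextual-modulation patterns (numbers 1-8):

* structure sets A, B: unidirectional rostro-caudal connections only;
* structure sets C-F: bidirectional closure of the five anatomical pairs;
* sets B, D, F additionally receive the contextual (chosen-vs-specified)
  difference as a direct driving input to PFC;
* sets C, D modulate only the forward (rostro-caudal) member of each
  modulated pair, sets E, F modulate both directions.

Matrices follow the usual DCM convention: ``A[i, j]`` is the coupling from
region ``j`` onto region ``i`` (column = source, row = target).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical region order used for every matrix in the package.
REGIONS: tuple[str, ...] = ("PFC", "PM", "preSMA", "M1")

STRUCTURE_SETS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")
MODULATION_PATTERNS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)

_IDX = {name: i for i, name in enumerate(REGIONS)}

# Anatomical skeleton: five region pairs; deliberately no direct PFC-M1 edge.
# Bidirectional closure of these pairs yields the ten intrinsic connections
# of the bidirectional structure sets.
ANATOMICAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("PFC", "PM"),
    ("PFC", "preSMA"),
    ("PM", "preSMA"),
    ("PM", "M1"),
    ("preSMA", "M1"),
)

# Directed edges of the unidirectional (feed-forward) skeleton.  The lateral
# preSMA -> PM direction is the default for the PM/preSMA pair; it is
# configurable through ``build_model(..., forward_edges=...)``.
FORWARD_EDGES: tuple[tuple[str, str], ...] = (
    ("PFC", "PM"),
    ("PFC", "preSMA"),
    ("preSMA", "PM"),
    ("PM", "M1"),
    ("preSMA", "M1"),
)

# Modulation patterns name the anatomical pairs whose connections carry the
# contextual bilinear effect.  1-4 modulate single pairs; 5 = rostral pairs,
# 6 = caudal pairs, 7 = rostral + caudal, 8 = all five pairs including the
# lateral PM/preSMA link.
MODULATED_PAIRS: dict[int, tuple[tuple[str, str], ...]] = {
    1: (("PFC", "PM"),),
    2: (("PFC", "preSMA"),),
    3: (("PM", "M1"),),
    4: (("preSMA", "M1"),),
    5: (("PFC", "PM"), ("PFC", "preSMA")),
    6: (("PM", "M1"), ("preSMA", "M1")),
    7: (("PFC", "PM"), ("PFC", "preSMA"), ("PM", "M1"), ("preSMA", "M1")),
    8: ANATOMICAL_PAIRS,
}

#: Structure sets with bidirectional intrinsic connectivity.
BIDIRECTIONAL_SETS = frozenset({"C", "D", "E", "F"})
#: Structure sets whose modulation acts on both directions of each pair.
RECIPROCAL_MODULATION_SETS = frozenset({"E", "F"})
#: Structure sets with the contextual difference as a second driving input.
CONTEXT_INPUT_SETS = frozenset({"B", "D", "F"})


@dataclass(frozen=True)
class ModelSpec:
    """One bilinear DCM: binary masks for the A, B and C matrices.

    ``a_mask`` marks directed intrinsic connections (off-diagonal only; the
    inhibitory self-connections live on the diagonal of the effective A
    matrix and are never counted as user-specified parameters).  ``b_mask``
    marks connections modulated by the contextual input and is always a
    subset of ``a_mask``.  ``c_mask`` has one column per driving input:
    column 0 is the onset of any trial, column 1 the contextual
    (chosen-vs-specified) difference.
    """

    model_id: str
    structure_set: str
    modulation_pattern: int
    a_mask: np.ndarray
    b_mask: np.ndarray
    c_mask: np.ndarray
    regions: tuple[str, ...] = field(default=REGIONS)

    def __post_init__(self) -> None:
        a = np.asarray(self.a_mask, dtype=int)
        b = np.asarray(self.b_mask, dtype=int)
        c = np.asarray(self.c_mask, dtype=int)
        if a.shape != (4, 4) or b.shape != (4, 4) or c.shape != (4, 2):
            raise ValueError("masks must be 4x4 (A, B) and 4x2 (C)")
        if np.any(np.diag(a)):
            raise ValueError("a_mask diagonal must be zero (self-connections are implicit)")
        if np.any(b & ~a):
            raise ValueError("b_mask must be a subset of a_mask")
        object.__setattr__(self, "a_mask", a)
        object.__setattr__(self, "b_mask", b)
        object.__setattr__(self, "c_mask", c)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "structure_set": self.structure_set,
            "pattern": self.modulation_pattern,
            "a_mask": self.a_mask.tolist(),
            "b_mask": self.b_mask.tolist(),
            "c_mask": self.c_mask.tolist(),
            "regions": list(self.regions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            model_id=d["model_id"],
            structure_set=d["structure_set"],
            modulation_pattern=int(d["pattern"]),
            a_mask=np.asarray(d["a_mask"], dtype=int),
            b_mask=np.asarray(d["b_mask"], dtype=int),
            c_mask=np.asarray(d["c_mask"], dtype=int),
            regions=tuple(d.get("regions", REGIONS)),
        )


def _edges_to_mask(edges) -> np.ndarray:
    mask = np.zeros((4, 4), dtype=int)
    for src, tgt in edges:
        mask[_IDX[tgt], _IDX[src]] = 1
    return mask


def build_model(
    structure_set: str,
    modulation_pattern: int,
    forward_edges: tuple[tuple[str, str], ...] = FORWARD_EDGES,
) -> ModelSpec:
    """Construct one model from its structure-set letter and pattern number.

    Parameters
    ----------
    structure_set : str
        One of ``A``-``F``.
    modulation_pattern : int
        One of ``1``-``8``.
    forward_edges : tuple of (source, target) pairs, optional
        Directed edges of the unidirectional skeleton; also defines which
        member of each pair counts as the "forward" direction for the
        forward-only modulation of sets C and D.
    """
    if structure_set not in STRUCTURE_SETS:
        raise ValueError(
            f"unknown structure set {structure_set!r}; valid sets are A-F"
        )
    if modulation_pattern not in MODULATION_PATTERNS:
        raise ValueError(
            f"unknown modulation pattern {modulation_pattern!r}; valid patterns are 1-8"
        )

    forward = _edges_to_mask(forward_edges)
    if structure_set in BIDIRECTIONAL_SETS:
        pair_mask = np.zeros((4, 4), dtype=int)
        for r1, r2 in ANATOMICAL_PAIRS:
            pair_mask[_IDX[r1], _IDX[r2]] = 1
            pair_mask[_IDX[r2], _IDX[r1]] = 1
        a_mask = pair_mask
    else:
        a_mask = forward

    # Connections eligible for modulation: both directions of each modulated
    # pair, restricted to the forward direction for sets C/D, then to edges
    # that actually exist in this structure.
    b_full = np.zeros((4, 4), dtype=int)
    for r1, r2 in MODULATED_PAIRS[modulation_pattern]:
        b_full[_IDX[r1], _IDX[r2]] = 1
        b_full[_IDX[r2], _IDX[r1]] = 1
    if structure_set in ("C", "D"):
        b_full &= forward
    b_mask = b_full & a_mask

    c_mask = np.zeros((4, 2), dtype=int)
    c_mask[_IDX["PFC"], 0] = 1
    if structure_set in CONTEXT_INPUT_SETS:
        c_mask[_IDX["PFC"], 1] = 1

    return ModelSpec(
        model_id=f"{structure_set}{modulation_pattern}",
        structure_set=structure_set,
        modulation_pattern=modulation_pattern,
        a_mask=a_mask,
        b_mask=b_mask,
        c_mask=c_mask,
    )


def build_model_space() -> list[ModelSpec]:
    """Enumerate all 48 models (6 structure sets x 8 modulation patterns)."""
    return [
        build_model(s, p) for s in STRUCTURE_SETS for p in MODULATION_PATTERNS
    ]


def count_parameters(model: ModelSpec) -> tuple[int, int, int]:
    """Counts of user-specified (intrinsic, bilinear, driving) parameters."""
    return (
        int(model.a_mask.sum()),
        int(model.b_mask.sum()),
        int(model.c_mask.sum()),
    )


def get_model(model_id: str) -> ModelSpec:
    """Look up one model of the 48 by id, e.g. ``"E2"``."""
    model_id = model_id.strip()
    if len(model_id) != 2:
        raise ValueError(f"model id must look like 'E2', got {model_id!r}")
    letter, digit = model_id[0], model_id[1]
    if not digit.isdigit():
        raise ValueError(f"model id must look like 'E2', got {model_id!r}")
    return build_model(letter, int(digit))
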