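"""Six-region face-perception network and the five-model modulatory space.

The network comprises left and right primary visual cortex (V1), occipital
face area (OFA) and fusiform face area (FFA).  All coupling matrices use the
convention **rows = target, columns = source**, so ``A[i, j]`` is the
influence of region ``j`` on region ``i``.

The endogenous (A) structure is shared by all models: driving visual input
enters V1 only; each V1 projects forward to the ipsilateral OFA and FFA;
OFA and FFA are bidirectionally coupled within each hemisphere; the only
interhemispheric connections are the homotopic OFA–OFA and FFA–FFA links
(V1 is treated as acallosal, and heterotopic links such as lOFA→rFFA are
excluded).  The five models M1–M5 differ only in which of these connections
the face-specific inputs are allowed to modulate (the B matrices), forming a
strictly nested family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "REGIONS",
    "DRIVING_INPUTS",
    "MODULATORY_INPUTS",
    "RegionSet",
    "ConnectivityStructure",
    "ModelSpec",
    "build_canonical_A",
    "build_canonical_C",
    "build_model_space",
    "validate_structure",
]

#: Canonical region order used for all matrix indexing.
REGIONS: tuple[str, ...] = ("lV1", "rV1", "lOFA", "rOFA", "lFFA", "rFFA")

#: Driving inputs: central / left / right visual stimulation (faces + objects).
DRIVING_INPUTS: tuple[str, ...] = ("CS", "LS", "RS")

#: Modulatory inputs: central / left / right *face* blocks.
MODULATORY_INPUTS: tuple[str, ...] = ("CF", "LF", "RF")

N_REGIONS = len(REGIONS)

_INDEX = {name: i for i, name in enumerate(REGIONS)}


def region_index(name: str) -> int:
    """Index of a region label in the canonical order."""
    return _INDEX[name]


@dataclass(frozen=True)
class RegionSet:
    """The ordered set of network nodes with hemisphere and area tags."""

    labels: tuple[str, ...] = REGIONS

    def __post_init__(self) -> None:
        if tuple(self.labels) != REGIONS:
            raise ValueError(
                f"region order is fixed to {REGIONS}, got {self.labels}"
            )

    @property
    def hemispheres(self) -> tuple[str, ...]:
        return tuple("left" if lbl[0] == "l" else "right" for lbl in self.labels)

    @property
    def areas(self) -> tuple[str, ...]:
        return tuple(lbl[1:] for lbl in self.labels)

    def index(self, label: str) -> int:
        return _INDEX[label]


@dataclass
class ConnectivityStructure:
    """Boolean structure masks for one model.

    Attributes
    ----------
    a_mask : (6, 6) bool array
        Endogenous connections (rows = target, columns = source).
    b_masks : dict of str -> (6, 6) bool array
        One mask per modulatory input (CF, LF, RF).
    c_mask : (6, 3) bool array
        Driving-input gains over (CS, LS, RS).
    """

    a_mask: np.ndarray
    b_masks: dict[str, np.ndarray]
    c_mask: np.ndarray

    def copy(self) -> "ConnectivityStructure":
        return ConnectivityStructure(
            a_mask=self.a_mask.copy(),
            b_masks={k: v.copy() for k, v in self.b_masks.items()},
            c_mask=self.c_mask.copy(),
        )


@dataclass
class ModelSpec:
    """One member of the model space (M1…M5)."""

    id: str
    structure: ConnectivityStructure
    driving_inputs: tuple[str, ...] = DRIVING_INPUTS
    modulatory_inputs: tuple[str, ...] = MODULATORY_INPUTS
    regions: tuple[str, ...] = REGIONS

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "regions": list(self.regions),
            "driving_inputs": list(self.driving_inputs),
            "modulatory_inputs": list(self.modulatory_inputs),
            "a_mask": self.structure.a_mask.astype(int).tolist(),
            "b_masks": {
                k: v.astype(int).tolist() for k, v in self.structure.b_masks.items()
            },
            "c_mask": self.structure.c_mask.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        structure = ConnectivityStructure(
            a_mask=np.asarray(d["a_mask"], dtype=bool),
            b_masks={k: np.asarray(v, dtype=bool) for k, v in d["b_masks"].items()},
            c_mask=np.asarray(d["c_mask"], dtype=bool),
        )
        return cls(
            id=d["id"],
            structure=structure,
            driving_inputs=tuple(d["driving_inputs"]),
            modulatory_inputs=tuple(d["modulatory_inputs"]),
            regions=tuple(d["regions"]),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelSpec":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    # -- convenience -------------------------------------------------------

    def n_free_neural(self) -> int:
        """Number of free neural parameters (A entries incl. the 6
        self-scalings, masked B entries, masked C entries)."""
        s = self.structure
        n_b = sum(int(m.sum()) for m in s.b_masks.values())
        return int(s.a_mask.sum()) + n_b + int(s.c_mask.sum())


def _edges(*pairs: tuple[str, str]) -> list[tuple[int, int]]:
    """(source, target) label pairs -> (row=target, col=source) indices."""
    return [(_INDEX[tgt], _INDEX[src]) for src, tgt in pairs]


# Directed inter-regional edges of the endogenous structure, grouped by role.
_FORWARD_V1_OFA = _edges(("lV1", "lOFA"), ("rV1", "rOFA"))
_FORWARD_V1_FFA = _edges(("lV1", "lFFA"), ("rV1", "rFFA"))
_OFA_TO_FFA = _edges(("lOFA", "lFFA"), ("rOFA", "rFFA"))
_FFA_TO_OFA = _edges(("lFFA", "lOFA"), ("rFFA", "rOFA"))
_INTERHEMI = _edges(
    ("lOFA", "rOFA"), ("rOFA", "lOFA"), ("lFFA", "rFFA"), ("rFFA", "lFFA")
)

#: Homotopic interhemispheric edges as (source, target) label pairs.
INTERHEMISPHERIC_EDGES: tuple[tuple[str, str], ...] = (
    ("lOFA", "rOFA"),
    ("rOFA", "lOFA"),
    ("lFFA", "rFFA"),
    ("rFFA", "lFFA"),
)


def build_canonical_A() -> np.ndarray:
    """Endogenous structure mask shared by all five models.

    Contains, per hemisphere, V1→OFA, V1→FFA and the bidirectional OFA↔FFA
    pair; the four homotopic interhemispheric edges; and all six
    self-connections (18 true entries in total).
    """
    a = np.zeros((N_REGIONS, N_REGIONS), dtype=bool)
    np.fill_diagonal(a, True)
    for i, j in (
        _FORWARD_V1_OFA + _FORWARD_V1_FFA + _OFA_TO_FFA + _FFA_TO_OFA + _INTERHEMI
    ):
        a[i, j] = True
    return a


def build_canonical_C() -> np.ndarray:
    """Driving-input mask: central stimulation enters both V1s, lateralised
    stimulation enters the contralateral V1 only."""
    c = np.zeros((N_REGIONS, len(DRIVING_INPUTS)), dtype=bool)
    c[_INDEX["lV1"], DRIVING_INPUTS.index("CS")] = True
    c[_INDEX["rV1"], DRIVING_INPUTS.index("CS")] = True
    c[_INDEX["rV1"], DRIVING_INPUTS.index("LS")] = True  # left hemifield -> right V1
    c[_INDEX["lV1"], DRIVING_INPUTS.index("RS")] = True  # right hemifield -> left V1
    return c


# Edge groups added at each step of the nested model family.
_MODEL_INCREMENTS: tuple[list[tuple[int, int]], ...] = (
    _INTERHEMI,       # M1: interhemispheric modulation only
    _OFA_TO_FFA,      # M2: + ipsilateral OFA->FFA
    _FFA_TO_OFA,      # M3: + FFA->OFA
    _FORWARD_V1_OFA,  # M4: + V1->OFA
    _FORWARD_V1_FFA,  # M5: + V1->FFA
)


def build_model_space() -> list[ModelSpec]:
    """The nested five-model space M1 ⊂ M2 ⊂ M3 ⊂ M4 ⊂ M5.

    All models share the canonical A and C masks; each step adds one group
    of modulatable edges (identically for each of the three face
    modulators), giving per-modulator edge counts 4, 6, 8, 10, 12.
    """
    a_mask = build_canonical_A()
    c_mask = build_canonical_C()
    specs: list[ModelSpec] = []
    b = np.zeros((N_REGIONS, N_REGIONS), dtype=bool)
    for k, increment in enumerate(_MODEL_INCREMENTS, start=1):
        for i, j in increment:
            b[i, j] = True
        structure = ConnectivityStructure(
            a_mask=a_mask.copy(),
            b_masks={m: b.copy() for m in MODULATORY_INPUTS},
            c_mask=c_mask.copy(),
        )
        specs.append(ModelSpec(id=f"M{k}", structure=structure))
    return specs


def get_model(model_id: str) -> ModelSpec:
    """Look up a single model (``"M1"`` … ``"M5"``) from the canonical space."""
    for spec in build_model_space():
        if spec.id == model_id:
            return spec
    raise KeyError(f"unknown model id {model_id!r}; expected M1..M5")


def validate_structure(spec: ModelSpec) -> list[str]:
    """Check a ModelSpec against the structural rules of the network.

    Returns a list of human-readable violations; an empty list means the
    structure is valid.  Violations are reported, never raised.
    """
    violations: list[str] = []
    s = spec.structure
    a = np.asarray(s.a_mask, dtype=bool)

    if a.shape != (N_REGIONS, N_REGIONS):
        return [f"a_mask has shape {a.shape}, expected {(N_REGIONS, N_REGIONS)}"]

    if not np.all(np.diag(a)):
        violations.append("a_mask diagonal must be all true (self-connections)")

    i_lv1, i_rv1 = _INDEX["lV1"], _INDEX["rV1"]
    if a[i_lv1, i_rv1] or a[i_rv1, i_lv1]:
        violations.append("V1 is acallosal: lV1<->rV1 entries must be false")

    # heterotopic interhemispheric entries (different hemisphere AND area)
    hemi = [lbl[0] for lbl in REGIONS]
    area = [lbl[1:] for lbl in REGIONS]
    for i in range(N_REGIONS):
        for j in range(N_REGIONS):
            if hemi[i] != hemi[j] and area[i] != area[j] and a[i, j]:
                violations.append(
                    f"heterotopic interhemispheric entry {REGIONS[j]}->{REGIONS[i]}"
                )

    # V1 receives no input from OFA/FFA
    for v1 in ("lV1", "rV1"):
        row = a[_INDEX[v1]].copy()
        row[_INDEX[v1]] = False
        if row.any():
            sources = [REGIONS[j] for j in np.flatnonzero(row)]
            violations.append(f"{v1} must not receive connections (from {sources})")

    off_diag_a = a & ~np.eye(N_REGIONS, dtype=bool)
    for name, b in s.b_masks.items():
        b = np.asarray(b, dtype=bool)
        if np.any(np.diag(b)):
            violations.append(f"B mask {name} modulates a self-connection")
        extra = b & ~off_diag_a
        if np.any(extra & ~np.eye(N_REGIONS, dtype=bool)):
            violations.append(
                f"B mask {name} has entries outside the off-diagonal A structure"
            )
    return violations


def mirror_permutation() -> np.ndarray:
    """Index permutation swapping left and right hemispheres."""
    perm = []
    for lbl in REGIONS:
        swapped = ("r" if lbl[0] == "l" else "l") + lbl[1:]
        perm.append(_INDEX[swapped])
    return np.array(perm)
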