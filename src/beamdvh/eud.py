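"""Equivalent uniform dose (gEUD), organ exponent registry, planning constraints.

The generalized EUD of a dose distribution is the power mean

    EUD = (Σ_v Δv · D_v^k)^(1/k)

over the percentage-volume grid, with ``k`` the organ-specific power-law
exponent: large k makes the EUD track the maximum dose (serial organs such as
the spinal cord), k = 1 gives the mean dose (parallel organs).  Where no
exponent is tabulated it can be derived from the organ's D50 tolerance dose as
k = 0.15 × D50.

Predicted EUDs carry a systematic organ-specific bias; the constraint
generator removes it with the training-set mean ratio of true to predicted
EUD (c_OAR) and tightens the result by a factor α slightly below 1 so that
the optimizer is pushed marginally past the prediction:

    cEUD' = α · c_OAR · EUD'
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dvh import DVHCurve, STRUCTURE_VOCABULARY, max_dose

__all__ = [
    "KEntry",
    "KRegistry",
    "ConstraintSet",
    "default_registry",
    "eud",
    "resolve_k",
    "correction_factor",
    "corrected_eud_constraint",
    "corrected_max_dose_constraint",
]

DEFAULT_ALPHA = 0.97

#: Power-law exponents by organ category.  A planning organ-at-risk volume
#: (PRV) shares its parent organ's exponent; bilateral organs share one entry.
_DEFAULT_K = {
    "spinal_cord": 10.0,
    "brainstem": 9.8,
    "optic_nerve": 9.8,
    "optic_chiasm": 9.8,
    "larynx": 6.8,
    "lens": 2.0,
    "parotid": 3.9,
}

D50_RULE_FACTOR = 0.15


@dataclass(frozen=True)
class KEntry:
    k: Optional[float] = None
    d50_gy: Optional[float] = None

    def __post_init__(self):
        if self.k is not None and self.k <= 0:
            raise ValueError("k must be positive (target-type negative k unsupported)")
        if self.d50_gy is not None and self.d50_gy <= 0:
            raise ValueError("d50_gy must be positive")


def _canonical_organ(structure_id: str) -> str:
    """Map a structure label to its organ category (strip PRV and laterality)."""
    name = structure_id
    if name.endswith("_prv"):
        name = name[: -len("_prv")]
    if name.endswith(("_l", "_r")):
        name = name[:-2]
    return name


@dataclass
class KRegistry:
    """Organ category -> EUD exponent mapping, with the D50 fallback rule."""

    entries: Dict[str, KEntry] = field(default_factory=dict)

    def resolve(self, structure_id: str) -> float:
        if structure_id not in STRUCTURE_VOCABULARY:
            raise KeyError(f"unknown structure {structure_id!r}")
        organ = _canonical_organ(structure_id)
        entry = self.entries.get(organ)
        if entry is None:
            raise KeyError(f"no exponent available for {structure_id!r}")
        if entry.k is not None:
            return entry.k
        if entry.d50_gy is not None:
            return D50_RULE_FACTOR * entry.d50_gy
        raise KeyError(f"no exponent available for {structure_id!r}")

    @classmethod
    def from_mapping(cls, mapping: Dict[str, dict]) -> "KRegistry":
        return cls(
            entries={
                organ: KEntry(k=entry.get("k"), d50_gy=entry.get("d50_gy"))
                for organ, entry in mapping.items()
            }
        )

    @classmethod
    def from_file(cls, path) -> "KRegistry":
        """Load from YAML or JSON: ``{organ: {k: float, d50_gy: float?}}``."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            mapping = yaml.safe_load(text)
        else:
            mapping = json.loads(text)
        return cls.from_mapping(mapping)

    def to_file(self, path) -> None:
        path = Path(path)
        mapping = {
            organ: {
                k: v
                for k, v in (("k", e.k), ("d50_gy", e.d50_gy))
                if v is not None
            }
            for organ, e in self.entries.items()
        }
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(mapping, sort_keys=True))
        else:
            path.write_text(json.dumps(mapping, indent=2, sort_keys=True))


def default_registry() -> KRegistry:
    """Registry shipped with the package (no D50 defaults; supply your own)."""
    return KRegistry(entries={o: KEntry(k=k) for o, k in _DEFAULT_K.items()})


def resolve_k(registry: KRegistry, structure_id: str) -> float:
    return registry.resolve(structure_id)


def eud(dvh: DVHCurve, k: float) -> float:
    """Generalized EUD of a quantile curve.

    Computed as Dmax · (Σ Δv (D_v/Dmax)^k)^(1/k) so that k ≈ 10 with doses
    ~70 Gy stays far from overflow.  An all-zero curve has EUD 0.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    dmax = max_dose(dvh)
    if dmax == 0.0:
        return 0.0
    ratios = dvh.doses / dmax
    s = float(np.sum(dvh.dv * np.power(ratios, k)))
    return dmax * s ** (1.0 / k)


def correction_factor(train_pairs: Sequence[Tuple[float, float]]) -> float:
    """Mean ratio of true to predicted EUD over the training set (c_OAR)."""
    if len(train_pairs) == 0:
        raise ValueError("correction factor needs at least one training pair")
    true = np.array([p[0] for p in train_pairs], dtype=float)
    pred = np.array([p[1] for p in train_pairs], dtype=float)
    if np.any(pred <= 0):
        raise ValueError("degenerate prediction")
    return float(np.mean(true / pred))


def corrected_eud_constraint(
    eud_pred: float, c_oar: float, alpha: float = DEFAULT_ALPHA
) -> float:
    """Bias-corrected, tightened EUD constraint cEUD' = α · c_OAR · EUD'."""
    if eud_pred <= 0 or c_oar <= 0:
        raise ValueError("inputs must be positive")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return alpha * c_oar * eud_pred


def corrected_max_dose_constraint(
    dmax_pred: float,
    train_pairs: Sequence[Tuple[float, float]],
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Corrected maximum-dose constraint (same correction recipe as the EUD)."""
    c_max = correction_factor(train_pairs)
    return corrected_eud_constraint(dmax_pred, c_max, alpha)


#: organ categories for which a corrected maximum-dose constraint is emitted
MAX_DOSE_ORGANS = ("spinal_cord", "lens")


@dataclass
class ConstraintRow:
    patient_id: str
    structure_id: str
    constraint_type: str  # "eud" | "max_dose"
    value_gy: float
    k: Optional[float]
    c_oar: float
    alpha: float
    predicted_gy: float


@dataclass
class ConstraintSet:
    """Per-patient-organ corrected constraints ready for planner export."""

    rows: List[ConstraintRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "structure_id": r.structure_id,
                    "constraint_type": r.constraint_type,
                    "value_gy": r.value_gy,
                    "k": r.k,
                    "c_oar": r.c_oar,
                    "alpha": r.alpha,
                }
                for r in self.rows
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_constraints(
    predicted_curves: Dict[Tuple[str, str], DVHCurve],
    registry: KRegistry,
    train_eud_pairs: Dict[str, Sequence[Tuple[float, float]]],
    train_dmax_pairs: Optional[Dict[str, Sequence[Tuple[float, float]]]] = None,
    alpha: float = DEFAULT_ALPHA,
) -> ConstraintSet:
    """Assemble the full constraint set for a cohort of predicted curves.

    ``train_eud_pairs`` maps organ category -> (true, predicted) EUD pairs
    from the training set; ``train_dmax_pairs`` likewise for maximum dose
    (used only for organs in :data:`MAX_DOSE_ORGANS`).
    """
    cs = ConstraintSet()
    for (pid, sid), curve in sorted(predicted_curves.items()):
        organ = _canonical_organ(sid)
        k = registry.resolve(sid)
        e = eud(curve, k)
        c = correction_factor(train_eud_pairs[organ])
        cs.rows.append(
            ConstraintRow(
                patient_id=pid,
                structure_id=sid,
                constraint_type="eud",
                value_gy=corrected_eud_constraint(e, c, alpha),
                k=k,
                c_oar=c,
                alpha=alpha,
                predicted_gy=e,
            )
        )
        if train_dmax_pairs is not None and organ in MAX_DOSE_ORGANS:
            dmax = max_dose(curve)
            c_max = correction_factor(train_dmax_pairs[organ])
            cs.rows.append(
                ConstraintRow(
                    patient_id=pid,
                    structure_id=sid,
                    constraint_type="max_dose",
                    value_gy=corrected_eud_constraint(dmax, c_max, alpha),
                    k=None,
                    c_oar=c_max,
                    alpha=alpha,
                    predicted_gy=dmax,
                )
            )
    return cs
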