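"""Multiphase assembly: static per-phase features and change-rate (delta) features.

The static vector of a case holds 12 + 24*4 + 7 = 115 features: the 12
first-order statistics and the 7 morphology descriptors enter once (taken
from the reference arterial-early phase — geometry does not change between
phases, and the intensity histogram of the baseline phase anchors the
static description), while the 24 direction-averaged texture features
enter once per contrast phase (24 x 4 = 96).

Dynamics live in the delta features: between each of the 3 adjacent phase
pairs, every one of the 36 per-phase dynamic features (12 first-order +
24 texture) yields a relative change rate

    x~_{l-r} = (x_l - x_r) / x_r

giving 36*3 = 108 delta features and 115 + 108 = 223 features in total.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .imaging_io import PHASE_ORDER
from .radiomics import FIRST_ORDER_NAMES, MORPHOLOGY_NAMES, TEXTURE_NAMES, PhaseFeatureBlock

logger = logging.getLogger(__name__)

#: The 36 per-phase dynamic features (delta features are built from these).
DYNAMIC_NAMES = FIRST_ORDER_NAMES + TEXTURE_NAMES

#: Adjacent phase transitions in acquisition order (reference r -> later l).
TRANSITIONS = tuple(zip(PHASE_ORDER[:-1], PHASE_ORDER[1:]))

#: Reference phase for the once-per-case static blocks.
REFERENCE_PHASE = PHASE_ORDER[0]

N_STATIC = (
    len(FIRST_ORDER_NAMES)
    + len(TEXTURE_NAMES) * len(PHASE_ORDER)
    + len(MORPHOLOGY_NAMES)
)  # 12 + 24*4 + 7 = 115
N_DELTA = len(DYNAMIC_NAMES) * len(TRANSITIONS)  # 36*3 = 108


def change_rate(x_r: float, x_l: float, eps: float = 1e-12) -> float:
    """Relative change of a feature from reference phase r to later phase l.

    Returns ``(x_l - x_r) / x_r``. A (near-)zero reference value yields 0
    with a logged warning rather than an infinity, keeping the design
    matrix finite; this arises only for degenerate inputs.
    """
    if not (np.isfinite(x_r) and np.isfinite(x_l)):
        raise ValueError(f"change_rate requires finite inputs, got x_r={x_r}, x_l={x_l}")
    if abs(x_r) < eps:
        logger.warning("change_rate: reference value %.3g below eps=%.1g; returning 0", x_r, eps)
        return 0.0
    return (x_l - x_r) / x_r


@dataclasses.dataclass(frozen=True)
class CaseFeatureVector:
    """One case's 115 static + 108 delta features, with its binary group."""

    case_id: str
    static: dict[str, float]
    delta: dict[str, float]
    label: int  # +1 response (ease), -1 non-response (relief)

    def as_dict(self) -> dict[str, float]:
        out = dict(self.static)
        out.update(self.delta)
        return out


def assemble_case(
    case_id: str,
    blocks: dict[str, PhaseFeatureBlock],
    label: int,
) -> CaseFeatureVector:
    """Assemble one case's feature vector from its four phase blocks.

    Naming: texture features are ``<feature>__<phase>`` per phase;
    first-order features enter once as ``<feature>__<reference phase>``;
    morphology keeps its bare name; deltas are
    ``<feature>__delta_<r>_<l>`` for adjacent phases r -> l.
    """
    missing = [p for p in PHASE_ORDER if p not in blocks]
    if missing:
        raise ValueError(f"case {case_id!r}: missing phase blocks {missing}")
    static: dict[str, float] = {}
    for name in FIRST_ORDER_NAMES:
        static[f"{name}__{REFERENCE_PHASE}"] = blocks[REFERENCE_PHASE].first_order[name]
    for phase in PHASE_ORDER:
        for name in TEXTURE_NAMES:
            static[f"{name}__{phase}"] = blocks[phase].texture[name]
    morph = blocks[REFERENCE_PHASE].morphology
    for name in MORPHOLOGY_NAMES:
        static[name] = morph[name]
    delta: dict[str, float] = {}
    for r, l in TRANSITIONS:
        dyn_r, dyn_l = blocks[r].as_dict(), blocks[l].as_dict()
        for name in DYNAMIC_NAMES:
            delta[f"{name}__delta_{r}_{l}"] = change_rate(dyn_r[name], dyn_l[name])
    assert len(static) == N_STATIC and len(delta) == N_DELTA
    return CaseFeatureVector(case_id=case_id, static=static, delta=delta, label=int(label))


def cohort_table(cases: list[CaseFeatureVector]) -> tuple[pd.DataFrame, pd.Series]:
    """Stack case vectors into a cases x features table plus the label vector."""
    if not cases:
        raise ValueError("empty cohort")
    X = pd.DataFrame([c.as_dict() for c in cases], index=[c.case_id for c in cases])
    y = pd.Series([c.label for c in cases], index=X.index, name="label")
    return X, y


FEATURE_SET_NAMES = ("S1", "S2", "S3", "S4", "S5")


def feature_set_columns() -> dict[str, list[str]]:
    """Column membership of the five nested feature sets.

    S1 morphology only (7); S2 static dynamic features (108: 12 reference-
    phase first-order + 24 texture x 4 phases); S3 delta features (108);
    S4 all static = S2 + morphology (115); S5 everything (223).
    """
    morph = list(MORPHOLOGY_NAMES)
    per_phase = [f"{n}__{REFERENCE_PHASE}" for n in FIRST_ORDER_NAMES] + [
        f"{n}__{p}" for p in PHASE_ORDER for n in TEXTURE_NAMES
    ]
    delta = [f"{n}__delta_{r}_{l}" for (r, l) in TRANSITIONS for n in DYNAMIC_NAMES]
    static = per_phase + morph
    return {
        "S1": morph,
        "S2": per_phase,
        "S3": delta,
        "S4": static,
        "S5": static + delta,
    }


def build_feature_sets(X: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Slice the full cohort table into the five named feature sets."""
    if X.shape[0] == 0:
        raise ValueError("empty cohort")
    cols = feature_set_columns()
    missing = set(cols["S5"]) - set(X.columns)
    if missing:
        raise ValueError(f"cohort table lacks expected columns, e.g. {sorted(missing)[:3]}")
    return {name: X[c] for name, c in cols.items()}
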