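"""The candidate mechanism space and marker read-out.

Three binary/ternary attributes of the differentiation process are left open
and combined into 12 candidate mechanisms:

* whether an intermediate mesendoderm germ layer exists (two-stage scheme)
  or hESC differentiate directly into the terminal lineages;
* whether mesoderm expresses the surface marker CXCR4;
* which phenotypes are allowed to proliferate (all; endoderm plus the
  uncommitted hESC/mesendoderm pool; uncommitted only).

The named mechanisms of interest are A = ``ME+/CX+/EU``, B = ``ME+/CX-/EU``
and C = ``ME+/CX+/A``.

The marker read-out maps per-phenotype live counts to the two experimentally
observed fractions: Sox17 marks visceral plus definitive endoderm; CXCR4 marks
definitive endoderm and mesendoderm, plus mesoderm iff the mechanism says so.
Marker positivity is commitment-gated: only committed cells count.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Mapping

import numpy as np

__all__ = [
    "Phenotype",
    "ProliferationScope",
    "MechanismConfig",
    "MECHANISM_A",
    "MECHANISM_B",
    "MECHANISM_C",
    "enumerate_mechanisms",
    "get_mechanism",
    "proliferation_allowed",
    "marker_fractions",
    "UndefinedFractionError",
]


class Phenotype(IntEnum):
    """Cell phenotypes. HESC and MESENDODERM are uncommitted at their stage;
    the other three are terminal (absorbing)."""

    HESC = 0
    MESENDODERM = 1
    VISCERAL_ENDODERM = 2
    DEFINITIVE_ENDODERM = 3
    MESODERM = 4


#: Terminal phenotypes: once committed, frozen forever.
TERMINAL = (Phenotype.VISCERAL_ENDODERM, Phenotype.DEFINITIVE_ENDODERM, Phenotype.MESODERM)


class ProliferationScope(str, Enum):
    ALL = "ALL"
    ENDODERM_AND_UNCOMMITTED = "ENDODERM_AND_UNCOMMITTED"
    UNCOMMITTED_ONLY = "UNCOMMITTED_ONLY"


_SCOPE_CODE = {
    ProliferationScope.ALL: "A",
    ProliferationScope.ENDODERM_AND_UNCOMMITTED: "EU",
    ProliferationScope.UNCOMMITTED_ONLY: "U",
}
_CODE_SCOPE = {v: k for k, v in _SCOPE_CODE.items()}


class UndefinedFractionError(ValueError):
    """Marker fractions requested for an empty (zero live cells) population."""


@dataclass(frozen=True)
class MechanismConfig:
    """One of the 12 candidate differentiation mechanisms."""

    include_mesendoderm: bool
    cxcr4_in_mesoderm: bool
    proliferation_scope: ProliferationScope

    @property
    def id(self) -> str:
        """Canonical id string, e.g. ``"ME+/CX-/EU"``."""
        me = "ME+" if self.include_mesendoderm else "ME-"
        cx = "CX+" if self.cxcr4_in_mesoderm else "CX-"
        return f"{me}/{cx}/{_SCOPE_CODE[self.proliferation_scope]}"

    def lineage_slots(self, stage: int) -> tuple[Phenotype, ...]:
        """Lineages competing for propensity updates at the given stage.

        Stage 1 with mesendoderm: {mesendoderm, visceral endoderm}.
        Stage 1 without: the single-stage set {definitive endoderm, visceral
        endoderm, mesoderm} directly from hESC.  Stage 2 (only reachable with
        mesendoderm): {definitive endoderm, mesoderm}.
        """
        if stage == 1:
            if self.include_mesendoderm:
                return (Phenotype.MESENDODERM, Phenotype.VISCERAL_ENDODERM)
            return (
                Phenotype.DEFINITIVE_ENDODERM,
                Phenotype.VISCERAL_ENDODERM,
                Phenotype.MESODERM,
            )
        if stage == 2:
            if not self.include_mesendoderm:
                raise ValueError("stage 2 does not exist without mesendoderm")
            return (Phenotype.DEFINITIVE_ENDODERM, Phenotype.MESODERM)
        raise ValueError(f"invalid stage {stage}")


MECHANISM_A = "ME+/CX+/EU"
MECHANISM_B = "ME+/CX-/EU"
MECHANISM_C = "ME+/CX+/A"


def enumerate_mechanisms() -> list[MechanismConfig]:
    """All 2 x 2 x 3 candidate mechanisms in stable canonical order."""
    out = []
    for me in (True, False):
        for cx in (True, False):
            for scope in ProliferationScope:
                out.append(MechanismConfig(me, cx, scope))
    return out


def get_mechanism(mech: "MechanismConfig | str") -> MechanismConfig:
    """Resolve an id string like ``"ME+/CX-/EU"`` to its config (idempotent)."""
    if isinstance(mech, MechanismConfig):
        return mech
    parts = mech.split("/")
    try:
        me_s, cx_s, scope_s = parts
        if me_s not in ("ME+", "ME-") or cx_s not in ("CX+", "CX-"):
            raise KeyError(mech)
        return MechanismConfig(me_s == "ME+", cx_s == "CX+", _CODE_SCOPE[scope_s])
    except (ValueError, KeyError):
        raise ValueError(
            f"unknown mechanism id {mech!r}; expected e.g. 'ME+/CX-/EU' "
            f"(scope codes: A, EU, U)"
        ) from None


def proliferation_allowed(phenotype: Phenotype, mech: "MechanismConfig | str") -> bool:
    """Whether the mechanism permits division of cells of this phenotype.

    The uncommitted pool (hESC and mesendoderm) proliferates under every
    scope; ``ENDODERM_AND_UNCOMMITTED`` adds definitive endoderm (visceral
    endoderm, an extra-embryonic phenotype, is excluded); ``ALL`` permits
    every phenotype.
    """
    mech = get_mechanism(mech)
    phenotype = Phenotype(phenotype)
    scope = mech.proliferation_scope
    if scope is ProliferationScope.ALL:
        return True
    if phenotype in (Phenotype.HESC, Phenotype.MESENDODERM):
        return True
    if scope is ProliferationScope.ENDODERM_AND_UNCOMMITTED:
        return phenotype is Phenotype.DEFINITIVE_ENDODERM
    return False


def allowed_mask(mech: "MechanismConfig | str") -> np.ndarray:
    """Boolean lookup ``mask[phenotype]`` of proliferation permission."""
    mech = get_mechanism(mech)
    return np.array([proliferation_allowed(p, mech) for p in Phenotype], dtype=bool)


def marker_fractions(
    counts: Mapping[Phenotype, int], mech: "MechanismConfig | str"
) -> tuple[float, float]:
    """Map per-phenotype live counts to (frac_sox17, frac_cxcr4).

    Raises
    ------
    UndefinedFractionError
        If the live total is zero.
    """
    mech = get_mechanism(mech)
    live = sum(counts.values())
    if live <= 0:
        raise UndefinedFractionError("marker fractions undefined for an empty population")
    ve = counts.get(Phenotype.VISCERAL_ENDODERM, 0)
    de = counts.get(Phenotype.DEFINITIVE_ENDODERM, 0)
    me = counts.get(Phenotype.MESENDODERM, 0)
    meso = counts.get(Phenotype.MESODERM, 0)
    sox = (ve + de) / live
    cx = (de + me + (meso if mech.cxcr4_in_mesoderm else 0)) / live
    return sox, cx


def marker_fraction_arrays(
    phen_counts: np.ndarray, live: np.ndarray, mech: "MechanismConfig | str"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized marker read-out over snapshots.

    ``phen_counts`` has shape (..., 5) indexed by :class:`Phenotype`; ``live``
    the matching leading shape.  Snapshots with zero live cells yield 0 in
    both fractions (the extinct-run convention; the scalar
    :func:`marker_fractions` raises instead).
    """
    mech = get_mechanism(mech)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where(live > 0, live, 1)
        sox = (phen_counts[..., Phenotype.VISCERAL_ENDODERM]
               + phen_counts[..., Phenotype.DEFINITIVE_ENDODERM]) / denom
        cx_counts = (phen_counts[..., Phenotype.DEFINITIVE_ENDODERM]
                     + phen_counts[..., Phenotype.MESENDODERM])
        if mech.cxcr4_in_mesoderm:
            cx_counts = cx_counts + phen_counts[..., Phenotype.MESODERM]
        cx = cx_counts / denom
    sox = np.where(live > 0, sox, 0.0)
    cx = np.where(live > 0, cx, 0.0)
    return sox, cx
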