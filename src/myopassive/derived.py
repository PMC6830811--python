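"""Derived mechanical quantities of a fitted bundle model.

From a :class:`~myopassive.laws.BundleModel` this module produces the
two standard summaries: the load-bearing table (per-component stress in
force per unit bundle area, i.e. volume-fraction weighted, plus the
percentage of total tension each component carries at a set of
sarcomere lengths) and tangent-stiffness curves (numerical slope of
nominal stress with respect to stretch, per component or total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .laws import (
    BundleModel,
    FibreLawParams,
    TangLawParams,
    ZhangLawParams,
    bundle_uniaxial_stress,
    ecm_uniaxial_stress,
    fibre_stress,
    tang_stress,
    zhang_stress,
)

__all__ = [
    "LoadBearingRow",
    "TangentPoint",
    "load_bearing_table",
    "load_bearing_frame",
    "tangent_stiffness_curve",
    "tangent_frame",
]


@dataclass(frozen=True)
class LoadBearingRow:
    """One length of the load-bearing table.

    Stresses are force per unit *bundle* area (α-weighted).  Percentages
    normalise the two components to their sum; where the total stress is
    zero they are undefined and the row is flagged.
    """

    sarcomere_length: float
    ecm_stress: float
    fibre_stress: float
    ecm_percent: float
    fibre_percent: float
    undefined: bool = False


def load_bearing_table(model: BundleModel, lengths) -> list:
    """Per-component bundle stresses and load-bearing percentages."""
    rows = []
    for L in np.atleast_1d(np.asarray(lengths, dtype=float)):
        if L <= 0:
            raise DomainError("lengths must be positive")
        comp = bundle_uniaxial_stress(float(L), model)
        fib = comp.fast + comp.slow
        total = fib + comp.ecm
        if total == 0.0:
            rows.append(LoadBearingRow(float(L), comp.ecm, fib,
                                       float("nan"), float("nan"),
                                       undefined=True))
        else:
            rows.append(LoadBearingRow(
                float(L), comp.ecm, fib,
                100.0 * comp.ecm / total, 100.0 * fib / total))
    return rows


def load_bearing_frame(rows, rounded: bool = True) -> pd.DataFrame:
    """Tabular view; 1 decimal for kPa and % when ``rounded`` (raw otherwise)."""
    frame = pd.DataFrame(
        [(r.sarcomere_length, r.ecm_stress, r.fibre_stress,
          r.ecm_percent, r.fibre_percent, r.undefined) for r in rows],
        columns=["sarcomere_length_um", "ecm_stress_kpa", "fibre_stress_kpa",
                 "ecm_percent", "fibre_percent", "undefined"],
    )
    if rounded:
        for col in ("ecm_stress_kpa", "fibre_stress_kpa",
                    "ecm_percent", "fibre_percent"):
            frame[col] = frame[col].round(1)
    return frame


@dataclass(frozen=True)
class TangentPoint:
    """Tangent modulus dP/dλ at one length; flagged if one-sided."""

    length: float
    modulus: float
    one_sided: bool = False


def _stress_callable(obj, component: str):
    """Return (P(L) callable, slack lengths with a kink) for the input."""
    if callable(obj):
        return obj, ()
    if isinstance(obj, FibreLawParams):
        return (lambda L: fibre_stress(L, obj)), (obj.L0,)
    if isinstance(obj, TangLawParams):
        # quadratic law is C1 at slack: no kink
        return (lambda L: tang_stress(L, obj)), ()
    if isinstance(obj, ZhangLawParams):
        return (lambda L: zhang_stress(L, obj)), (obj.L0,)
    if isinstance(obj, BundleModel):
        if component == "total":
            fn = lambda L: bundle_uniaxial_stress(L, obj).total
            kinks = (obj.fast.L0, obj.slow.L0)
        elif component == "fibres":
            fn = lambda L: bundle_uniaxial_stress(L, obj).fast + \
                bundle_uniaxial_stress(L, obj).slow
            kinks = (obj.fast.L0, obj.slow.L0)
        elif component == "ecm":
            fn = lambda L: ecm_uniaxial_stress(L, obj.ecm) * obj.fractions.alpha_c
            kinks = ()
        else:
            raise DomainError(f"unknown component {component!r}")
        return fn, kinks
    raise DomainError("expected a callable, law parameters, or a BundleModel")


def tangent_stiffness_curve(stress, lengths, reference_length,
                            rel_step: float = 1e-4,
                            component: str = "total") -> list:
    """Numerical tangent modulus dP/dλ along a length grid.

    The stretch coordinate is λ = L / reference_length, a required
    explicit argument — reported moduli always state this convention.
    Central differences with relative step ``rel_step``; where the
    stencil straddles a fibre slack length (a kink of the law) a
    one-sided difference on the containing side is used and the point
    is flagged.
    """
    if reference_length <= 0:
        raise DomainError("reference_length must be positive")
    fn, kinks = _stress_callable(stress, component)
    out = []
    for L in np.atleast_1d(np.asarray(lengths, dtype=float)):
        if L <= 0:
            raise DomainError("lengths must be positive")
        h = rel_step * float(L)  # step in L; dλ = h / reference_length
        lo, hi = L - h, L + h
        straddle = [s for s in kinks if lo < s < hi and not np.isclose(s, L)]
        at_kink = any(np.isclose(s, L) for s in kinks)
        if at_kink or straddle:
            s = L if at_kink else straddle[0]
            if L >= s:  # kink at or below L: forward difference
                dPdL = (fn(L + h) - fn(L)) / h
            else:
                dPdL = (fn(L) - fn(L - h)) / h
            out.append(TangentPoint(float(L), float(dPdL) * reference_length,
                                    one_sided=True))
        else:
            dPdL = (fn(hi) - fn(lo)) / (2.0 * h)
            out.append(TangentPoint(float(L), float(dPdL) * reference_length))
    return out


def tangent_frame(points, rounded: bool = True) -> pd.DataFrame:
    frame = pd.DataFrame(
        [(p.length, p.modulus, p.one_sided) for p in points],
        columns=["sarcomere_length_um", "tangent_modulus_kpa", "one_sided"])
    if rounded:
        frame["tangent_modulus_kpa"] = frame["tangent_modulus_kpa"].round(1)
    return frame
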