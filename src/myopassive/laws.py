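"""Passive-stress constitutive laws for skeletal-muscle fibres, ECM and bundles.

Single permeabilised fibres bear passive tension through intracellular
structures (chiefly titin); within a bundle the surrounding extracellular
matrix (ECM) adds a second, stiffer contribution.  This module evaluates
the scalar (uniaxial) and tensorial (first Piola-Kirchhoff) forms of the
laws used to separate the two:

* an exponential fibre law ``P(λ) = A [exp(λ² − 1) − 1]`` with stretch
  ``λ = L / L0`` measured on sarcomere length, clamped to zero in
  shortening (fibres have negligible compressive stiffness);
* two literature alternatives for the fibre parallel elastic element —
  a quadratic law ``4 P0 (λ − 1)²`` and the Zhang exponential law
  ``2 P0 a A (λ − 1) exp[a (λ − 1)²]``;
* an isotropic hyperelastic ECM law, as a full PK1 tensor and in its
  uniaxial incompressible scalar form
  ``β I1 (λ − 1/λ²) exp(λ² + 2/λ − 3)`` with ``I1 = λ² + 2/λ``;
* the volume-fraction (rule-of-mixtures) bundle composition of fast
  fibres, slow fibres and ECM.

All stresses are nominal (force per undeformed area) in kPa; lengths are
sarcomere lengths in μm.  Functions are vectorised over the length
argument and preserve scalar inputs.

Note on the two ECM forms: the uniaxial (1,1) component of the tensor
law equals 2/3 of the scalar law at every stretch (the scalar form, used
for fitting, omits the deviatoric 2/3).  Both forms are kept as defined;
the constant :data:`UNIAXIAL_TENSOR_SCALAR_RATIO` records the ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError

__all__ = [
    "FibreLawParams",
    "TangLawParams",
    "ZhangLawParams",
    "ECMParams",
    "VolumeFractions",
    "BundleModel",
    "DeformationState",
    "BundleStressComponents",
    "fibre_stress",
    "fibre_stress_from_stretch",
    "fibre_tangent_modulus",
    "tang_stress",
    "zhang_stress",
    "zhang_initial_modulus",
    "ecm_uniaxial_stress",
    "bundle_uniaxial_stress",
    "ecm_stress_tensor",
    "bundle_stress_tensor",
    "uniaxial_incompressible_F",
    "UNIAXIAL_TENSOR_SCALAR_RATIO",
]

#: Ratio of the (1,1) PK1 component of the tensor ECM law to the scalar
#: uniaxial ECM law under uniaxial incompressible stretch.  The tensor
#: deviator contributes a factor (λ − λ/3·I1/λ²·...) that reduces to
#: (2/3)(λ − 1/λ²); the scalar form carries (λ − 1/λ²) directly.
UNIAXIAL_TENSOR_SCALAR_RATIO = 2.0 / 3.0


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise DomainError(message)


@dataclass(frozen=True)
class FibreLawParams:
    """Exponential fibre law parameters.

    A : stress scale in kPa; half of the initial tangent modulus.
    L0 : slack sarcomere length in μm.
    """

    A: float
    L0: float

    def __post_init__(self):
        _require(self.A > 0, f"A must be > 0, got {self.A}")
        _require(self.L0 > 0, f"L0 must be > 0, got {self.L0}")


@dataclass(frozen=True)
class TangLawParams:
    """Quadratic fibre law parameters (P0 = maximum isometric stress, kPa)."""

    P0: float
    L0: float

    def __post_init__(self):
        _require(self.P0 > 0, f"P0 must be > 0, got {self.P0}")
        _require(self.L0 > 0, f"L0 must be > 0, got {self.L0}")


@dataclass(frozen=True)
class ZhangLawParams:
    """Zhang exponential fibre law parameters.

    P0 : maximum isometric stress, kPa.  a, A : dimensionless shape/scale.
    """

    P0: float
    a: float
    A: float
    L0: float

    def __post_init__(self):
        _require(self.P0 > 0, f"P0 must be > 0, got {self.P0}")
        _require(self.a > 0, f"a must be > 0, got {self.a}")
        _require(self.A > 0, f"A must be > 0, got {self.A}")
        _require(self.L0 > 0, f"L0 must be > 0, got {self.L0}")


@dataclass(frozen=True)
class ECMParams:
    """Isotropic ECM law parameters.

    beta : nonlinearity scale in kPa (use :meth:`from_mpa` for MPa input).
    k_v : bulk modulus in kPa; only active for non-isochoric deformation.
    L0b : stress-free sarcomere length of the bundle, μm.
    """

    beta: float
    k_v: float
    L0b: float

    def __post_init__(self):
        _require(self.beta > 0, f"beta must be > 0, got {self.beta}")
        _require(self.k_v >= 0, f"k_v must be >= 0, got {self.k_v}")
        _require(self.L0b > 0, f"L0b must be > 0, got {self.L0b}")

    @classmethod
    def from_mpa(cls, beta_mpa: float, k_v_mpa: float, L0b: float) -> "ECMParams":
        """Build from stress parameters given in MPa (converted to kPa)."""
        return cls(beta=beta_mpa * 1e3, k_v=k_v_mpa * 1e3, L0b=L0b)


@dataclass(frozen=True)
class VolumeFractions:
    """Cross-sectional volume fractions of fast fibres, slow fibres, ECM."""

    alpha_f: float
    alpha_s: float
    alpha_c: float

    _SUM_TOL = 1e-9

    def __post_init__(self):
        for name, v in (("alpha_f", self.alpha_f),
                        ("alpha_s", self.alpha_s),
                        ("alpha_c", self.alpha_c)):
            _require(0.0 <= v <= 1.0, f"{name} must lie in [0, 1], got {v}")
        total = self.alpha_f + self.alpha_s + self.alpha_c
        _require(abs(total - 1.0) <= self._SUM_TOL,
                 f"volume fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class BundleModel:
    """Rule-of-mixtures bundle: fast fibres + slow fibres + ECM.

    ``fibre_direction`` is the undeformed fibre orientation n0 (unit
    vector); the tensor evaluation maps it through the deformation
    gradient.  The bundle reference configuration is the ECM stress-free
    state, so an axial stretch λ corresponds to sarcomere length
    ``L = λ · L0b``.
    """

    fast: FibreLawParams
    slow: FibreLawParams
    ecm: ECMParams
    fractions: VolumeFractions
    fibre_direction: tuple = (1.0, 0.0, 0.0)

    def __post_init__(self):
        n0 = np.asarray(self.fibre_direction, dtype=float)
        _require(n0.shape == (3,), "fibre_direction must be a 3-vector")
        _require(abs(np.linalg.norm(n0) - 1.0) <= 1e-12,
                 "fibre_direction must be a unit vector")

    @property
    def n0(self) -> np.ndarray:
        return np.asarray(self.fibre_direction, dtype=float)


@dataclass(frozen=True)
class DeformationState:
    """A material-point deformation gradient and its derived invariants."""

    F: tuple  # nested 3x3 tuple or array-like; stored immutably

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        _require(F.shape == (3, 3), "F must be 3x3")
        _require(np.linalg.det(F) > 0, "det F must be > 0")
        object.__setattr__(self, "F", tuple(map(tuple, F)))

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.F, dtype=float)

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.matrix))

    @property
    def C(self) -> np.ndarray:
        F = self.matrix
        return F @ F.T

    @property
    def I1(self) -> float:
        return float(np.trace(self.C))

    @property
    def I1_bar(self) -> float:
        return self.J ** (-2.0 / 3.0) * self.I1


def _as_lengths(L):
    """Validate lengths (> 0, finite); return (array, was_scalar)."""
    arr = np.asarray(L, dtype=float)
    scalar = arr.ndim == 0
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError("sarcomere lengths must be positive and finite")
    return arr, scalar


def _ret(value, scalar):
    return float(value) if scalar else value


def fibre_stress_from_stretch(lam, A):
    """Exponential fibre law as a function of stretch (clamped below 1)."""
    lam = np.asarray(lam, dtype=float)
    with np.errstate(over="ignore"):
        stress = A * np.expm1(lam ** 2 - 1.0)
    return np.where(lam >= 1.0, stress, 0.0)


def fibre_stress(L, params: FibreLawParams):
    """Passive nominal stress (kPa) of a fibre at sarcomere length L (μm)."""
    arr, scalar = _as_lengths(L)
    return _ret(fibre_stress_from_stretch(arr / params.L0, params.A), scalar)


def fibre_tangent_modulus(L, params: FibreLawParams):
    """Analytic tangent modulus dP/dλ of the exponential fibre law (kPa).

    The right limit at the slack length is 2A; the value 2A is returned
    at λ exactly 1 (the left derivative is 0 — the law is C0 there).
    """
    arr, scalar = _as_lengths(L)
    lam = arr / params.L0
    with np.errstate(over="ignore"):
        mod = 2.0 * params.A * lam * np.exp(lam ** 2 - 1.0)
    return _ret(np.where(lam >= 1.0, mod, 0.0), scalar)


def tang_stress(L, params: TangLawParams):
    """Quadratic fibre law: 4 P0 (λ − 1)² in tension, 0 in shortening."""
    arr, scalar = _as_lengths(L)
    lam = arr / params.L0
    stress = 4.0 * params.P0 * (lam - 1.0) ** 2
    return _ret(np.where(lam >= 1.0, stress, 0.0), scalar)


def zhang_stress(L, params: ZhangLawParams):
    """Zhang law: 2 P0 a A (λ − 1) exp[a (λ − 1)²] in tension, 0 below slack."""
    arr, scalar = _as_lengths(L)
    lam = arr / params.L0
    with np.errstate(over="ignore"):
        stress = (2.0 * params.P0 * params.a * params.A * (lam - 1.0)
                  * np.exp(params.a * (lam - 1.0) ** 2))
    return _ret(np.where(lam >= 1.0, stress, 0.0), scalar)


def zhang_initial_modulus(params: ZhangLawParams) -> float:
    """Initial tangent modulus of the Zhang law, 2 P0 a A (kPa)."""
    return 2.0 * params.P0 * params.a * params.A


def ecm_uniaxial_stress(L, ecm: ECMParams):
    """Uniaxial incompressible ECM nominal stress (kPa), scalar form.

    ``β I1 (λ − 1/λ²) exp(λ² + 2/λ − 3)`` with λ = L/L0b and
    I1 = λ² + 2/λ.  No compression clamp: the expression is evaluated
    for all λ > 0 and is negative for λ < 1.
    """
    arr, scalar = _as_lengths(L)
    lam = arr / ecm.L0b
    i1 = lam ** 2 + 2.0 / lam
    with np.errstate(over="ignore"):
        stress = ecm.beta * i1 * (lam - 1.0 / lam ** 2) * np.exp(i1 - 3.0)
    return _ret(stress, scalar)


@dataclass(frozen=True)
class BundleStressComponents:
    """α-weighted stress addends of a bundle; total is their exact sum."""

    fast: object
    slow: object
    ecm: object

    @property
    def total(self):
        return self.fast + self.slow + self.ecm


def bundle_uniaxial_stress(L, model: BundleModel) -> BundleStressComponents:
    """Bundle nominal stress at sarcomere length L, decomposed by component.

    Returns the three volume-fraction-weighted addends
    (α_f·P_fast, α_s·P_slow, α_c·P_ecm); ``.total`` is their sum.
    """
    arr, scalar = _as_lengths(L)
    fr = model.fractions
    fast = fr.alpha_f * fibre_stress_from_stretch(arr / model.fast.L0, model.fast.A)
    slow = fr.alpha_s * fibre_stress_from_stretch(arr / model.slow.L0, model.slow.A)
    ecm = fr.alpha_c * ecm_uniaxial_stress(arr, model.ecm)
    if scalar:
        return BundleStressComponents(float(fast), float(slow), float(ecm))
    return BundleStressComponents(fast, slow, np.asarray(ecm))


def _as_state(state) -> DeformationState:
    if isinstance(state, DeformationState):
        return state
    return DeformationState(F=state)


def ecm_stress_tensor(state, ecm: ECMParams) -> np.ndarray:
    """First Piola-Kirchhoff stress tensor (kPa) of the isotropic ECM law.

    ``P = k_v (J² − 1) F⁻ᵀ + β Ī1 exp(Ī1 − 3) J^(−2/3) (F − (1/3) I1 F⁻ᵀ)``
    where Ī1 = J^(−2/3) I1.  The volumetric term vanishes identically for
    isochoric deformation (J = 1).
    """
    st = _as_state(state)
    F = st.matrix
    J = st.J
    try:
        F_inv_T = np.linalg.inv(F).T
    except np.linalg.LinAlgError as exc:  # pragma: no cover - det>0 guards this
        raise DomainError("singular deformation gradient") from exc
    I1 = st.I1
    I1_bar = st.I1_bar
    vol = ecm.k_v * (J ** 2 - 1.0) * F_inv_T
    iso = (ecm.beta * I1_bar * math.exp(I1_bar - 3.0) * J ** (-2.0 / 3.0)
           * (F - (I1 / 3.0) * F_inv_T))
    return vol + iso


def bundle_stress_tensor(state, model: BundleModel) -> np.ndarray:
    """First Piola-Kirchhoff stress tensor (kPa) of the bundle composition.

    Fibre stretch is |F·n0| relative to the bundle stress-free state, so
    the sarcomere length seen by each fibre law is ``|F·n0| · L0b``.  The
    fibre term is ``(α_f P_f + α_s P_s) n ⊗ n0`` with n = F·n0/|F·n0|;
    the ECM term is α_c times the tensor ECM law.
    """
    st = _as_state(state)
    F = st.matrix
    n0 = model.n0
    Fn0 = F @ n0
    lam_axial = float(np.linalg.norm(Fn0))
    if lam_axial <= 0:
        raise DomainError("degenerate fibre mapping |F n0| = 0")
    n = Fn0 / lam_axial
    L = lam_axial * model.ecm.L0b
    fr = model.fractions
    p_fast = fr.alpha_f * float(fibre_stress_from_stretch(L / model.fast.L0, model.fast.A))
    p_slow = fr.alpha_s * float(fibre_stress_from_stretch(L / model.slow.L0, model.slow.A))
    fibre_term = (p_fast + p_slow) * np.outer(n, n0)
    return fibre_term + fr.alpha_c * ecm_stress_tensor(st, model.ecm)


def uniaxial_incompressible_F(lam: float, axis: int = 0) -> np.ndarray:
    """Isochoric uniaxial deformation gradient diag(λ, λ^(−1/2), λ^(−1/2))."""
    if lam <= 0:
        raise DomainError("stretch must be positive")
    d = np.full(3, lam ** (-0.5))
    d[axis] = lam
    return np.diag(d)
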