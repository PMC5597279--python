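"""Constitutive models: linear elasticity and a phase-diagram superelastic NiTi model.

The superelastic model is a small-strain, rate-independent phase-transformation
model of the Boyd--Lagoudas/Auricchio family.  The martensite volume fraction
``xi`` is the single internal scalar; transformation is driven by the von Mises
equivalent stress, with linear stress--temperature transformation lines

    forward  (A -> M):  q = C_M * (T - Ms) ... C_M * (T - Mf)
    reverse  (M -> A):  q = C_A * (T - As) ... C_A * (T - Af)

and linear hardening in ``xi`` between the start and finish lines.  Elastic
moduli follow a Reuss (series) mixture of the austenite and martensite moduli.
Above ``Af`` the model is superelastic: any mechanically closed loading path
returns to zero stress and zero martensite fraction, enclosing a dissipative
flag-shaped hysteresis loop.

Units: stresses in MPa, moduli stored in GPa (as conventionally tabulated),
temperatures in K, strains dimensionless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "SMAParams",
    "MaterialState",
    "LinearElastic",
    "TransformationStresses",
    "transformation_stresses",
    "integrate_point_1d",
    "uniaxial_path",
    "integrate_point_3d",
    "sma_update",
    "drive_uniaxial_stress_3d",
    "calibrate_from_curve",
    "load_material",
    "builtin_material",
    "builtin_table",
    "elastic_D",
]

# Voigt bookkeeping: strain vectors are engineering ([e11,e22,e33,g23,g13,g12]),
# stress vectors are [s11,s22,s33,t23,t13,t12].
_TENSOR_W = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


class TransformationStresses(NamedTuple):
    """Critical uniaxial transformation stresses (MPa) at the operating temperature."""

    forward_start: float
    forward_finish: float
    reverse_start: float
    reverse_finish: float


@dataclass(frozen=True)
class SMAParams:
    """Superelastic NiTi material constants.

    Moduli in GPa, temperatures in K, slopes in MPa/K, ``H`` is the maximum
    uniaxial transformation strain (dimensionless), ``sigma_y`` in MPa.
    """

    E_A: float = 37.0
    E_M: float = 42.0
    nu: float = 0.33
    Ms: float = 263.0
    Mf: float = 243.0
    As: float = 270.0
    Af: float = 280.0
    C_M: float = 7.0
    C_A: float = 7.0
    H: float = 0.04
    sigma_y: float = 1011.0
    T_op: float = 310.0
    name: str = "NiTi"

    def __post_init__(self) -> None:
        if not (self.Mf < self.Ms < self.As < self.Af):
            raise ValueError(
                f"transformation temperatures must satisfy Mf < Ms < As < Af, "
                f"got Mf={self.Mf}, Ms={self.Ms}, As={self.As}, Af={self.Af}"
            )
        for attr in ("E_A", "E_M", "C_M", "C_A", "H", "sigma_y"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("nu must lie in (0, 0.5)")

    @property
    def E_A_mpa(self) -> float:
        return self.E_A * 1000.0

    @property
    def E_M_mpa(self) -> float:
        return self.E_M * 1000.0

    def modulus_mpa(self, xi):
        """Reuss mixture modulus at martensite fraction ``xi`` (MPa)."""
        return 1.0 / ((1.0 - xi) / self.E_A_mpa + xi / self.E_M_mpa)

    def shear_mpa(self, xi):
        return self.modulus_mpa(xi) / (2.0 * (1.0 + self.nu))

    def bulk_mpa(self, xi):
        return self.modulus_mpa(xi) / (3.0 * (1.0 - 2.0 * self.nu))


@dataclass
class MaterialState:
    """Internal state of a superelastic material point.

    ``eps`` is the total engineering Voigt strain, ``eps_t`` the transformation
    strain (engineering Voigt), ``xi`` the martensite volume fraction.
    ``direction`` records the sign of the 1D transformation branch.
    """

    eps: np.ndarray = field(default_factory=lambda: np.zeros(6))
    eps_t: np.ndarray = field(default_factory=lambda: np.zeros(6))
    xi: float = 0.0
    direction: float = 0.0

    def copy(self) -> "MaterialState":
        return MaterialState(self.eps.copy(), self.eps_t.copy(), float(self.xi), self.direction)

    def validate(self) -> None:
        if not (-1e-12 <= self.xi <= 1.0 + 1e-12):
            raise ValueError(f"martensite fraction out of [0, 1]: xi={self.xi}")


@dataclass(frozen=True)
class LinearElastic:
    """Isotropic linear elastic material; ``E`` in MPa."""

    E: float
    nu: float = 0.3
    sigma_y: float | None = None
    name: str = "linear"

    def D(self) -> np.ndarray:
        return elastic_D(self.E, self.nu)


def elastic_D(E: float, nu: float) -> np.ndarray:
    """Isotropic elasticity matrix (6x6, engineering Voigt), E in MPa."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def transformation_stresses(
    params: SMAParams, require_superelastic: bool = True
) -> TransformationStresses:
    """Critical uniaxial stresses of the transformation lines at ``T_op``.

    Clausius--Clapeyron construction: each transformation temperature maps to a
    critical stress through the corresponding stress--temperature slope.  With
    ``require_superelastic=True`` (default) an operating temperature at or
    below ``Af`` raises, because the stress-induced loop does not close there.
    """
    T = params.T_op
    if require_superelastic and T <= params.Af:
        raise ValueError(
            f"superelastic loop undefined: T_op={T} K must exceed Af={params.Af} K"
        )
    return TransformationStresses(
        forward_start=params.C_M * (T - params.Ms),
        forward_finish=params.C_M * (T - params.Mf),
        reverse_start=params.C_A * (T - params.As),
        reverse_finish=params.C_A * (T - params.Af),
    )


# ----------------------------------------------------------------------------
# 1D integration (reference implementation, scalar return mapping)
# ----------------------------------------------------------------------------

_MAX_STRAIN_DEFAULT = 0.06
_TOL = 1e-8
_MAX_ITER = 50


def integrate_point_1d(
    params: SMAParams,
    state: MaterialState,
    strain_increment: float,
    max_strain: float = _MAX_STRAIN_DEFAULT,
) -> tuple[float, MaterialState]:
    """Advance a uniaxial superelastic material point by a strain increment.

    Returns the axial stress (MPa) and the updated state.  The axial strain is
    stored in ``state.eps[0]`` and the axial transformation strain in
    ``state.eps_t[0]``.
    """
    state.validate()
    ts = transformation_stresses(params)
    sms, smf, srs, srf = ts
    dfwd = smf - sms
    drev = srs - srf

    eps = float(state.eps[0]) + strain_increment
    if abs(eps) > max_strain:
        raise ValueError(f"|strain|={abs(eps):.4g} exceeds the {max_strain:.2%} cap")

    xi0 = float(state.xi)
    H = params.H

    def stress_at(x: float, direction: float) -> float:
        return params.modulus_mpa(x) * (eps - direction * H * x)

    # Trial with frozen internal variables.
    sigma_tr = params.modulus_mpa(xi0) * (eps - float(state.eps_t[0]))
    direction = state.direction if xi0 > _TOL else (np.sign(sigma_tr) or 0.0)

    xi = xi0
    if direction != 0.0 and np.sign(sigma_tr) == direction or xi0 <= _TOL:
        s_tr = abs(sigma_tr)
        if s_tr - (sms + dfwd * xi0) > _TOL and xi0 < 1.0:
            # forward transformation: solve |sigma(x)| = sms + dfwd * x
            if direction == 0.0:
                direction = np.sign(sigma_tr)

            def g(x: float) -> float:
                return direction * stress_at(x, direction) - (sms + dfwd * x)

            xi = 1.0 if g(1.0) >= 0.0 else brentq(g, xi0, 1.0, xtol=_TOL, maxiter=200)
        elif (srf + drev * xi0) - s_tr > _TOL and xi0 > 0.0:
            # reverse transformation: solve |sigma(x)| = srf + drev * x
            def h(x: float) -> float:
                return direction * stress_at(x, direction) - (srf + drev * x)

            xi = 0.0 if h(0.0) <= 0.0 else brentq(h, 0.0, xi0, xtol=_TOL, maxiter=200)

    if xi <= _TOL and xi0 <= _TOL:
        direction = 0.0
    sigma = params.modulus_mpa(xi) * (eps - direction * H * xi)

    new = state.copy()
    new.eps[0] = eps
    new.eps_t[0] = direction * H * xi
    new.xi = float(np.clip(xi, 0.0, 1.0))
    new.direction = direction if new.xi > _TOL else 0.0
    new.validate()
    return float(sigma), new


def uniaxial_path(
    params: SMAParams, strains: np.ndarray, state: MaterialState | None = None
) -> np.ndarray:
    """Stress response (MPa) along a prescribed axial strain path."""
    state = MaterialState() if state is None else state.copy()
    out = np.empty(len(strains))
    for i, e in enumerate(strains):
        sigma, state = integrate_point_1d(params, state, e - float(state.eps[0]))
        out[i] = sigma
    return out


# ----------------------------------------------------------------------------
# 3D vectorized update (used by the FE solver at every Gauss point)
# ----------------------------------------------------------------------------


def _dev_strain(eps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deviatoric tensor components and volumetric strain of an engineering
    Voigt strain array (..., 6)."""
    vol = eps[..., :3].sum(axis=-1)
    dev = np.empty_like(eps)
    dev[..., :3] = eps[..., :3] - (vol / 3.0)[..., None]
    dev[..., 3:] = eps[..., 3:] / 2.0
    return dev, vol


def _eq_strain(dev: np.ndarray) -> np.ndarray:
    return np.sqrt(np.maximum(2.0 / 3.0 * (dev**2 * _TENSOR_W).sum(axis=-1), 0.0))


def sma_update(
    params: SMAParams,
    eps: np.ndarray,
    eps_t_old: np.ndarray,
    xi_old: np.ndarray,
    n_bisect: int = 80,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized 3D return mapping for arrays of material points.

    Parameters are total engineering Voigt strain ``eps`` (..., 6), previous
    transformation strain (..., 6) and previous martensite fraction (...,).
    Returns (stress (...,6) MPa, xi_new, eps_t_new).  Transformation is driven
    by the von Mises equivalent stress; the forward flow direction is the trial
    deviator direction (radial return); the reverse branch shrinks the stored
    transformation strain proportionally.  The scalar consistency equations are
    solved by vectorized bisection to ~1e-8 relative tolerance.
    """
    eps = np.asarray(eps, dtype=float)
    eps_t_old = np.asarray(eps_t_old, dtype=float)
    xi_old = np.asarray(xi_old, dtype=float)
    ts = transformation_stresses(params)
    sms, smf, srs, srf = ts
    dfwd, drev = smf - sms, srs - srf
    H = params.H

    e_tr = eps - eps_t_old
    dev_tr, _ = _dev_strain(e_tr)
    eq_tr = _eq_strain(dev_tr)
    q_tr = 3.0 * params.shear_mpa(xi_old) * eq_tr

    fwd = (q_tr > sms + dfwd * xi_old + _TOL) & (xi_old < 1.0)
    rev = (q_tr < srf + drev * xi_old - _TOL) & (xi_old > 0.0) & ~fwd

    xi_new = xi_old.copy()
    eps_t_new = eps_t_old.copy()

    if np.any(fwd):
        idx = np.nonzero(fwd)
        eq_f, xi_f = eq_tr[idx], xi_old[idx]

        def psi(x):
            return 3.0 * params.shear_mpa(x) * (eq_f - H * (x - xi_f)) - (sms + dfwd * x)

        hi_sat = psi(np.ones_like(xi_f)) >= 0.0
        lo, hi = xi_f.copy(), np.ones_like(xi_f)
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            pos = psi(mid) > 0.0
            lo = np.where(pos, mid, lo)
            hi = np.where(pos, hi, mid)
        x = np.where(hi_sat, 1.0, 0.5 * (lo + hi))
        n_dir = dev_tr[idx] / np.maximum(eq_tr[idx], 1e-300)[..., None]
        n_eng = n_dir * np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
        eps_t_new[idx] = eps_t_old[idx] + (H * (x - xi_f))[..., None] * n_eng
        xi_new[idx] = x

    if np.any(rev):
        idx = np.nonzero(rev)
        eps_r, et_r, xi_r = eps[idx], eps_t_old[idx], xi_old[idx]

        def q_of(x):
            et = et_r * (x / np.maximum(xi_r, 1e-300))[..., None]
            dev, _ = _dev_strain(eps_r - et)
            return 3.0 * params.shear_mpa(x) * _eq_strain(dev)

        def chi(x):
            return q_of(x) - (srf + drev * x)

        lo_sat = chi(np.zeros_like(xi_r)) <= 0.0  # fully reverted
        lo, hi = np.zeros_like(xi_r), xi_r.copy()
        # chi decreases with x on the reverse branch: chi(hi)<0, chi(lo)>=0
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            pos = chi(mid) > 0.0
            lo = np.where(pos, mid, lo)
            hi = np.where(pos, hi, mid)
        x = np.where(lo_sat, 0.0, 0.5 * (lo + hi))
        eps_t_new[idx] = et_r * (x / np.maximum(xi_r, 1e-300))[..., None]
        xi_new[idx] = x

    xi_new = np.clip(xi_new, 0.0, 1.0)
    e_el = eps - eps_t_new
    dev, vol = _dev_strain(e_el)
    G = params.shear_mpa(xi_new)
    K = params.bulk_mpa(xi_new)
    sigma = np.empty_like(eps)
    sigma[..., :3] = 2.0 * G[..., None] * dev[..., :3] + (K * vol)[..., None]
    sigma[..., 3:] = 2.0 * G[..., None] * dev[..., 3:]
    return sigma, xi_new, eps_t_new


def integrate_point_3d(
    params: SMAParams,
    state: MaterialState,
    strain_increment: np.ndarray,
    tangent: bool = True,
    h: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray | None, MaterialState]:
    """Single-point 3D update: returns (stress, consistent tangent, new state).

    The tangent is computed by central differences of the return mapping and
    symmetrized; in elastic branches it coincides with the isotropic elasticity
    matrix at the current martensite fraction.
    """
    state.validate()
    d_eps = np.asarray(strain_increment, dtype=float)
    if d_eps.shape != (6,):
        raise ValueError("strain increment must be a 6-vector (engineering Voigt)")
    eps = state.eps + d_eps
    sigma, xi, eps_t = sma_update(params, eps[None], state.eps_t[None], np.array([state.xi]))
    D = None
    if tangent:
        pert = np.tile(eps, (12, 1))
        for k in range(6):
            pert[2 * k, k] += h
            pert[2 * k + 1, k] -= h
        sp, _, _ = sma_update(
            params, pert, np.tile(state.eps_t, (12, 1)), np.full(12, state.xi)
        )
        D = (sp[0::2] - sp[1::2]).T / (2.0 * h)
        D = 0.5 * (D + D.T)
    new = MaterialState(eps=eps, eps_t=eps_t[0], xi=float(xi[0]), direction=state.direction)
    new.validate()
    return sigma[0], D, new


def drive_uniaxial_stress_3d(
    params: SMAParams,
    axial_strains: np.ndarray,
    axis: int = 0,
    tol: float = 1e-9,
) -> np.ndarray:
    """Axial stress along a uniaxial-stress path (lateral stresses iterated to zero).

    Used as the 1D/3D consistency oracle: the returned curve must match
    :func:`uniaxial_path` for the same axial strain history.
    """
    lat = [i for i in range(3) if i != axis]
    state = MaterialState()
    out = np.empty(len(axial_strains))
    eps = np.zeros(6)
    for i, ea in enumerate(axial_strains):
        eps[axis] = ea

        def residual(x):
            eps[lat[0]], eps[lat[1]] = x
            s, _, _ = sma_update(params, eps[None], state.eps_t[None], np.array([state.xi]))
            return np.array([s[0, lat[0]], s[0, lat[1]]])

        x = np.array([eps[lat[0]], eps[lat[1]]])
        for _ in range(80):
            r = residual(x)
            if np.abs(r).max() < tol * max(1.0, abs(out[i - 1]) if i else 1.0):
                break
            J = np.empty((2, 2))
            dh = 1e-8
            for k in range(2):
                xp = x.copy()
                xp[k] += dh
                J[:, k] = (residual(xp) - r) / dh
            x = x - np.linalg.solve(J, r)
        eps[lat[0]], eps[lat[1]] = x
        sigma, _, state = integrate_point_3d(params, state, eps - state.eps, tangent=False)
        out[i] = sigma[axis]
    return out


def calibrate_from_curve(
    strain: np.ndarray,
    stress: np.ndarray,
    params0: SMAParams,
) -> SMAParams:
    """Fit (C_M, C_A, H) to a measured uniaxial stress--strain loop.

    The moduli and transformation temperatures of ``params0`` are kept fixed;
    the slopes and the transformation strain magnitude are adjusted by least
    squares against the full loading/unloading history.
    """
    strain = np.asarray(strain, float)
    stress = np.asarray(stress, float)

    def resid(x):
        cm, ca, h = x
        try:
            p = replace(params0, C_M=cm, C_A=ca, H=h)
            return uniaxial_path(p, strain) - stress
        except ValueError:
            return np.full(len(strain), 1e6)

    res = least_squares(
        resid,
        x0=[params0.C_M, params0.C_A, params0.H],
        bounds=([0.5, 0.5, 0.005], [50.0, 50.0, 0.12]),
    )
    cm, ca, h = res.x
    return replace(params0, C_M=float(cm), C_A=float(ca), H=float(h))


# ----------------------------------------------------------------------------
# Material files
# ----------------------------------------------------------------------------


def _material_from_dict(d: dict):
    kind = d.get("model", "linear")
    if kind == "superelastic":
        keys = {f.name for f in SMAParams.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        return SMAParams(**{k: v for k, v in d.items() if k in keys})
    if kind == "linear":
        return LinearElastic(
            E=float(d["E"]),
            nu=float(d.get("nu", 0.3)),
            sigma_y=d.get("sigma_y"),
            name=d.get("name", "linear"),
        )
    raise ValueError(f"unknown material model '{kind}'")


def load_material(path: str):
    """Load a material from a flat key/value JSON file."""
    with open(path) as fh:
        return _material_from_dict(json.load(fh))


def builtin_table(name: str) -> dict:
    """Return one of the packaged material tables as a dict."""
    text = resources.files("stiffmatch.data").joinpath(f"{name}.json").read_text()
    return json.loads(text)


def builtin_material(name: str):
    """Load a named material from the packaged tables.

    Names: ``niti_superelastic``, ``ti6al4v``, ``niti_linear``, plus the linear
    mandible components (``cortical_host``, ``cancellous_host``,
    ``cortical_graft``, ``cancellous_graft``, ``teeth``, ``ligament``).
    """
    table = builtin_table("materials")
    if name not in table:
        raise KeyError(f"unknown builtin material '{name}'; have {sorted(table)}")
    return _material_from_dict(table[name])
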