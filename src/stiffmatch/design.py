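"""Stiffness-matching design loop: porosity selection and safety margins.

Given a target equivalent Young's modulus (the stiffness of the cortical bone
the hardware attaches to, 12 GPa by default), the design loop finds the pore
fraction of the tri-cylinder cell family at which the homogenized modulus of
the chosen alloy equals the target, then checks that the local stresses at the
safety strain (2% by default, the strain cortical bone can recover) stay below
the alloy's yield strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .homogenize import (
    EquivalentResponse,
    LocalStressReport,
    equivalent_curve,
    equivalent_modulus_gpa,
    local_stress_report,
    porosity_modulus_sweep,
)
from .lattice import UnitCell, max_porosity, solve_cell_for_porosity
from .materials import LinearElastic, SMAParams

__all__ = ["DesignSpec", "DesignResult", "SafetyReport", "solve_porosity_for_modulus", "safety_check"]


@dataclass(frozen=True)
class DesignSpec:
    """Inputs of one stiffness-matching design run."""

    target_modulus_gpa: float = 12.0
    material: object = None  # LinearElastic | SMAParams; default: superelastic NiTi
    pore_diameter: float = 1.0  # mm
    shell_thickness: float = 0.2  # mm
    safety_strain: float = 0.02
    resolution: int = 48  # voxels per cell edge for the refining solves
    coarse_resolution: int = 24  # voxels per edge for the bracketing sweep
    modulus_tol_gpa: float = 0.1
    max_refinements: int = 3  # porosity moves < 0.3 points per 0.1 GPa near the target

    def resolved_material(self):
        if self.material is not None:
            return self.material
        from .materials import builtin_material

        return builtin_material("niti_superelastic")


@dataclass
class DesignResult:
    porosity: float
    cell: UnitCell
    modulus_gpa: float
    target_gpa: float
    n_fine_solves: int
    sweep: object  # coarse bracketing table (DataFrame)

    def to_dict(self) -> dict:
        return {
            "porosity": self.porosity,
            "porosity_percent": 100.0 * self.porosity,
            "pore_diameter_mm": self.cell.d,
            "cell_edge_mm": self.cell.a,
            "equivalent_modulus_gpa": self.modulus_gpa,
            "target_modulus_gpa": self.target_gpa,
        }


@dataclass
class SafetyReport:
    max_local_stress_mpa: float
    raw_max_stress_mpa: float
    safety_factor: float
    passed: bool
    local: LocalStressReport
    response: EquivalentResponse


def _dense_modulus_gpa(material) -> float:
    if isinstance(material, SMAParams):
        return material.E_A
    return material.E / 1000.0


def solve_porosity_for_modulus(spec: DesignSpec) -> DesignResult:
    """Porosity (and dimensioned cell) matching the target equivalent modulus.

    A coarse-resolution porosity--modulus sweep brackets the target; secant
    refinement with full-resolution homogenizations then converges to the
    modulus tolerance.  The porosity--modulus map is strictly monotone, so the
    root is unique.
    """
    material = spec.resolved_material()
    dense = _dense_modulus_gpa(material)
    target = spec.target_modulus_gpa
    if not 0.0 < target <= dense:
        raise ValueError(f"target modulus {target} GPa outside (0, {dense}] GPa")
    if target == dense:
        return DesignResult(0.0, UnitCell(d=0.0, a=spec.pore_diameter), dense, target, 0, None)

    # coarse bracketing sweep over the attainable porosity range; composite
    # voxels keep the porosity -> modulus map continuous (a binary voxel set is
    # piecewise constant in porosity, which defeats root finding)
    phi_max = 0.90
    grid = np.linspace(0.15, phi_max, 9)
    sweep = porosity_modulus_sweep(material, grid, resolution=spec.coarse_resolution,
                                   d=spec.pore_diameter, composite=True)
    ok = sweep["modulus_gpa"].notna().to_numpy()
    e = sweep["modulus_gpa"].to_numpy()[ok]
    phi = sweep["porosity"].to_numpy()[ok]
    if target > e.max() or target < e.min():
        # extend toward the dense or empty limit as needed
        phi0 = 0.05 if target > e.max() else phi_max
    else:
        phi0 = float(np.interp(-target, -e, phi))  # e decreasing in phi

    def fine(p: float) -> float:
        cell = solve_cell_for_porosity(spec.pore_diameter, p)
        return equivalent_modulus_gpa(cell, material, spec.resolution, composite=True)

    # refinement stays in a local bracket around the coarse estimate: the
    # coarse map localizes the root, and discretization noise can otherwise
    # throw a step into under-resolved territory
    lo, hi = max(0.01, phi0 - 0.12), min(phi_max, phi0 + 0.12)
    slope = float(np.gradient(e, phi)[np.argmin(np.abs(phi - phi0))])

    # false-position refinement with bracket tracking: the porosity -> modulus
    # map is strictly decreasing, so once the target is straddled the bracket
    # shrinks monotonically
    stiff = None  # (p, e) with e > target  (porosity too low)
    soft = None  # (p, e) with e < target
    best = None
    p_cur = phi0
    n = 0
    while n < spec.max_refinements:
        e_cur = fine(p_cur)
        n += 1
        if best is None or abs(e_cur - target) < abs(best[1] - target):
            best = (p_cur, e_cur)
        if abs(e_cur - target) <= spec.modulus_tol_gpa:
            break
        if e_cur > target:
            stiff = (p_cur, e_cur)
        else:
            soft = (p_cur, e_cur)
        if stiff and soft:
            (p1, e1), (p2, e2) = stiff, soft
            p_cur = p1 + (target - e1) * (p2 - p1) / (e2 - e1)
        else:
            p_cur = float(np.clip(p_cur + (target - e_cur) / slope, lo, hi))

    p_best, e_best = best
    cell = solve_cell_for_porosity(spec.pore_diameter, p_best)
    return DesignResult(
        porosity=float(p_best),
        cell=cell,
        modulus_gpa=float(e_best),
        target_gpa=target,
        n_fine_solves=n,
        sweep=sweep,
    )


def safety_check(
    cell: UnitCell,
    material,
    safety_strain: float = 0.02,
    resolution: int | None = None,
    increments: int = 10,
) -> SafetyReport:
    """Drive the porous cell to the safety strain and compare the local
    maximum von Mises stress (singularity-filtered) against the yield strength.

    The safety factor is sigma_y / max local stress; the check passes when the
    factor exceeds 1.  For the superelastic alloy staying below yield also
    means the local transformation strains are recoverable on unloading.
    ``resolution=None`` applies the coarsest-adequate-mesh convention of
    :func:`stiffmatch.lattice.adequate_resolution` (local peak stresses at the
    re-entrant pore edges are mesh-dependent, so they are always reported at a
    stated mesh density).
    """
    from .lattice import adequate_resolution

    if resolution is None:
        resolution = adequate_resolution(cell)
    resp = equivalent_curve(cell, material, resolution=resolution,
                            max_strain=safety_strain, increments=increments)
    sigma_y = material.sigma_y
    rep = local_stress_report(resp, safety_strain, sigma_y=sigma_y)
    factor = sigma_y / rep.max_vm_filtered if rep.max_vm_filtered > 0 else np.inf
    return SafetyReport(
        max_local_stress_mpa=rep.max_vm_filtered,
        raw_max_stress_mpa=rep.max_vm,
        safety_factor=float(factor),
        passed=bool(factor > 1.0),
        local=rep,
        response=resp,
    )
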