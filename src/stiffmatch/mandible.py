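"""Reduced mandibular-reconstruction assembly.

A parametric, prismatic stand-in for a segmental mandibular reconstruction:
two host-bone segments (cortical shell over cancellous core) flank a resected
span bridged by a two-block "double barrel" fibular graft, held by one
inferior fixation plate and two superior mini-plates on the buccal face.
Screws are modelled as tie patches (merged nodes) between plate and bone; the
two host|graft cut planes are contact (healing, friction-0 endpoint) or bonded
(healed, friction-1 endpoint) interfaces.  Loads: a bite-force resultant on a
molar-region patch (60% of the healthy 526 N maximum for reconstructed
models), and optional plate pretension realized as an axial eigenstrain in the
plate mid-spans, equilibrated together with the bite load.

Axes: x = buccolingual (thickness), y = mesiodistal (length),
z = superoinferior (height).  All dimensions in mm, forces in N.

The model exists for *differential* comparisons (porous stiffness-matched NiTi
plates versus dense Ti-6Al-4V plates under identical loads); its absolute
stress magnitudes are not anatomical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fe import (
    FieldResult,
    Interface,
    LoadCase,
    VoxelMesh,
    assemble_and_solve_linear,
    solve_incremental_sma,
)
from .materials import LinearElastic, SMAParams, builtin_material

__all__ = [
    "AssemblyConfig",
    "ReducedAssembly",
    "LoadScenario",
    "SCENARIOS",
    "generate_assembly",
    "apply_scenario",
    "compare_models",
    "plate_material",
]

# region tags
HOST_CORT, HOST_CANC, GRAFT_CORT, GRAFT_CANC = 0, 1, 2, 3
PLATE_INF, PLATE_SUP_MES, PLATE_SUP_DIST = 4, 5, 6
REGIONS = {
    "host_cortical": HOST_CORT,
    "host_cancellous": HOST_CANC,
    "graft_cortical": GRAFT_CORT,
    "graft_cancellous": GRAFT_CANC,
    "plate_inferior": PLATE_INF,
    "plate_superior_mesial": PLATE_SUP_MES,
    "plate_superior_distal": PLATE_SUP_DIST,
}
PLATE_TAGS = (PLATE_INF, PLATE_SUP_MES, PLATE_SUP_DIST)


@dataclass(frozen=True)
class AssemblyConfig:
    """Geometry and discretization of the reduced assembly (mm)."""

    graft_length: float = 40.0  # resection span restored by the graft
    bone_width: float = 14.0  # buccolingual
    bone_height: float = 38.0  # superoinferior (graft restores full height)
    host_length: float = 24.0  # each host segment
    cortical_thickness: float = 2.0
    inferior_plate: tuple = (78.0, 4.0, 1.5)  # (length, height, thickness)
    superior_plate: tuple = (18.0, 2.8, 1.0)
    inferior_plate_z: float = 4.0  # bottom offset of the inferior plate
    superior_plate_z: float = 30.0
    screw_tie_radius: float = 2.2  # tie-patch radius around each screw axis
    spacing: tuple = (1.0, 2.0, 2.0)  # voxel size (dx, dy, dz)
    resolve_plates: bool = False  # True: plates meshed through the thickness
    bite_force: float = 526.0  # healthy maximum bite resultant
    bite_fraction: float = 0.60  # applied fraction for reconstructed models
    pretension: float = 100.0  # default per-plate pretension (N)
    resection: bool = True

    @staticmethod
    def coarse() -> "AssemblyConfig":
        """Desk-scale preset: membrane-equivalent plates (one voxel through
        the thickness, modulus scaled by real/modelled thickness)."""
        return AssemblyConfig()

    @staticmethod
    def fine() -> "AssemblyConfig":
        """Geometry-resolving preset: >= 3 voxels across the thinnest plate."""
        return AssemblyConfig(spacing=(1.0 / 3.0, 1.0, 1.0), resolve_plates=True)


@dataclass
class LoadScenario:
    """One loading case of the comparison study."""

    name: str
    bite: bool
    pretension: float  # N per plate
    interface_mode: str = "contact"  # 'contact' (healing) | 'bonded' (healed)


#: the study's loading cases: bite only (A), pretension only (B), both (C),
#: plus rest and the healthy (unresected) reference.  The default interface
#: mode is the healing-period friction-0 contact endpoint, where the plates
#: carry the load across the resection; the healed friction-1 endpoint is the
#: 'bonded' mode.
SCENARIOS = {
    "A": LoadScenario("A", bite=True, pretension=0.0, interface_mode="contact"),
    "B": LoadScenario("B", bite=False, pretension=100.0, interface_mode="contact"),
    "C": LoadScenario("C", bite=True, pretension=100.0, interface_mode="contact"),
    "rest": LoadScenario("rest", bite=False, pretension=0.0, interface_mode="contact"),
    "healthy": LoadScenario("healthy", bite=True, pretension=0.0, interface_mode="bonded"),
}


@dataclass
class ReducedAssembly:
    """Generated mesh plus the bookkeeping the load cases need."""

    mesh: VoxelMesh
    config: AssemblyConfig
    cut_pairs: list  # [(pairs, axis), ...] one per host|graft cut
    bite_nodes: np.ndarray
    fixed_faces: list  # node-id arrays of the fully fixed end faces
    plate_info: dict  # tag -> dict(elems_mid, area_mm2, thickness_scale)
    region_volumes: dict  # name -> mm^3

    def region_elems(self, tag: int) -> np.ndarray:
        return np.nonzero(self.mesh.elem_mat == tag)[0]


def _snap(length: float, h: float) -> int:
    n = max(1, round(length / h))
    if abs(n * h - length) > h + 1e-9:
        raise ValueError(f"dimension {length} mm not representable with voxel {h} mm")
    return n


def generate_assembly(config: AssemblyConfig | None = None) -> ReducedAssembly:
    """Build the voxel assembly, split the cut planes and attach the plates.

    With ``resolve_plates=True`` the voxel size must give at least 3 voxels
    across the thinnest plate; the membrane-equivalent mode represents each
    plate as a single voxel layer whose modulus is scaled by
    (real thickness) / (modelled thickness), preserving membrane stiffness.
    """
    cfg = config or AssemblyConfig()
    dx, dy, dz = cfg.spacing
    t_min = min(cfg.inferior_plate[2], cfg.superior_plate[2])
    if cfg.resolve_plates and dx > t_min / 3 + 1e-9:
        raise ValueError(
            f"under-resolved plates: voxel {dx} mm gives fewer than 3 voxels "
            f"across the {t_min} mm plate; reduce spacing or use the "
            "membrane-equivalent mode"
        )

    nxb = _snap(cfg.bone_width, dx)
    nz = _snap(cfg.bone_height, dz)
    n_host = _snap(cfg.host_length, dy)
    n_graft = _snap(cfg.graft_length, dy)
    ny = 2 * n_host + n_graft
    ly = ny * dy
    cut1, cut2 = n_host, n_host + n_graft

    def plate_xvox(t_real: float) -> int:
        return max(1, round(t_real / dx)) if cfg.resolve_plates else 1

    nx_inf = plate_xvox(cfg.inferior_plate[2])
    nx_sup = plate_xvox(cfg.superior_plate[2])
    nx = nxb + max(nx_inf, nx_sup)

    mat = -np.ones((nx, ny, nz), dtype=np.int32)
    # bone cross-section: cortical shell (x and z faces) over cancellous core
    xs = (np.arange(nxb) + 0.5) * dx
    zs = (np.arange(nz) + 0.5) * dz
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    tc = cfg.cortical_thickness
    cortical2d = (
        (X < tc)
        | (X > cfg.bone_width - tc)
        | (Z < tc)
        | (Z > cfg.bone_height - tc)
    )
    sec = np.where(cortical2d, 0, 1)  # 0 cortical, 1 cancellous
    for iy in range(ny):
        graft = cfg.resection and cut1 <= iy < cut2
        mat[:nxb, iy, :] = np.where(
            sec == 0,
            GRAFT_CORT if graft else HOST_CORT,
            GRAFT_CANC if graft else HOST_CANC,
        )

    # plates on the buccal face
    def add_plate(tag, length, height, z0, y_centre_mm, nx_t):
        n_len = _snap(length, dy)
        n_h = max(1, round(height / dz))
        iy0 = int(round(y_centre_mm / dy - n_len / 2))
        iz0 = int(round(z0 / dz))
        if iy0 < 0 or iy0 + n_len > ny or iz0 + n_h > nz:
            raise ValueError(f"plate {tag} does not fit the assembly")
        mat[nxb : nxb + nx_t, iy0 : iy0 + n_len, iz0 : iz0 + n_h] = tag
        return (iy0, iy0 + n_len, iz0, iz0 + n_h, nx_t)

    extents = {}
    if cfg.resection:
        extents[PLATE_INF] = add_plate(
            PLATE_INF, *cfg.inferior_plate[:2], cfg.inferior_plate_z, ly / 2, nx_inf
        )
        extents[PLATE_SUP_MES] = add_plate(
            PLATE_SUP_MES, *cfg.superior_plate[:2], cfg.superior_plate_z,
            cut1 * dy, nx_sup,
        )
        extents[PLATE_SUP_DIST] = add_plate(
            PLATE_SUP_DIST, *cfg.superior_plate[:2], cfg.superior_plate_z,
            cut2 * dy, nx_sup,
        )

    mesh = VoxelMesh(mat, spacing=cfg.spacing)

    # screw tie patches: (y, z) positions in mm on the plate-bone plane
    y1, y2 = cut1 * dy, cut2 * dy
    z_inf = cfg.inferior_plate_z + cfg.inferior_plate[1] / 2
    z_sup = cfg.superior_plate_z + cfg.superior_plate[1] / 2
    screws = {
        PLATE_INF: [(y1 - 16, z_inf), (y1 - 6, z_inf), (ly / 2 - 5, z_inf),
                    (ly / 2 + 5, z_inf), (y2 + 6, z_inf), (y2 + 16, z_inf)],
        PLATE_SUP_MES: [(y1 - 4.5, z_sup), (y1 + 4.5, z_sup)],
        PLATE_SUP_DIST: [(y2 - 4.5, z_sup), (y2 + 4.5, z_sup)],
    }

    cut_pairs = []
    if cfg.resection:
        # 1) detach the plates from the bone everywhere except the screw patches
        yc = (np.arange(ny) + 0.5) * dy
        zc = (np.arange(nz) + 0.5) * dz
        Yc, Zc = np.meshgrid(yc, zc, indexing="ij")
        attach_mask = np.zeros((ny, nz), dtype=bool)
        for tag, (a0, a1, b0, b1, _) in extents.items():
            attach_mask[a0:a1, b0:b1] = True
            for (sy, sz) in screws[tag]:
                attach_mask[
                    (Yc - sy) ** 2 + (Zc - sz) ** 2 <= cfg.screw_tie_radius**2
                ] = False
        mesh.split_plane(0, nxb, attach_mask, keep_side="plus")

        # 2) split the two host|graft cut planes through the bone columns
        xc = (np.arange(nx) + 0.5) * dx
        bone_cols = np.zeros((nx, nz), dtype=bool)
        bone_cols[xc < cfg.bone_width, :] = True
        for plane in (cut1, cut2):
            pairs = mesh.split_plane(1, plane, bone_cols)
            if len(pairs) == 0:
                raise ValueError("cut plane produced no interface pairs")
            cut_pairs.append((pairs, 1))

    # loads and supports: the bite resultant acts on the molar region — the
    # reconstructed (grafted) segment — at mid-span of the assembly, so the
    # occlusal load must cross the host|graft junctions; condyle end faces
    # are fully fixed
    bite_lo, bite_hi = ly / 2 - 5.0, ly / 2 + 5.0
    bite_nodes = mesh.nodes_where(
        lambda x, y, z: (np.abs(z - cfg.bone_height) < 1e-9)
        & (y >= bite_lo - 1e-9)
        & (y <= bite_hi + 1e-9)
        & (x <= cfg.bone_width + 1e-9)
    )
    fixed = [mesh.face_nodes(1, 0), mesh.face_nodes(1, 1)]

    plate_info = {}
    for tag, (a0, a1, b0, b1, nx_t) in extents.items():
        t_real = cfg.inferior_plate[2] if tag == PLATE_INF else cfg.superior_plate[2]
        t_model = nx_t * dx
        ymid_lo = (cut1 - 1) * dy if tag == PLATE_INF else None
        # mid-span elements carrying the pretension eigenstrain
        if tag == PLATE_INF:
            lo, hi = y1 - 2.0, y2 + 2.0
        elif tag == PLATE_SUP_MES:
            lo, hi = y1 - 4.0, y1 + 4.0
        else:
            lo, hi = y2 - 4.0, y2 + 4.0
        elems = mesh.elems_where(
            lambda x, y, z, lo=lo, hi=hi, tag=tag: (mesh.elem_mat == tag)
            & (y > lo)
            & (y < hi)
        )
        elems = elems[mesh.elem_mat[elems] == tag]
        plate_info[tag] = {
            "elems_mid": elems,
            "area_mm2": t_model * (b1 - b0) * dz,
            "thickness_scale": t_real / t_model,
        }

    vol = float(np.prod(cfg.spacing))
    region_volumes = {
        name: float((mesh.elem_mat == tag).sum()) * vol for name, tag in REGIONS.items()
    }
    return ReducedAssembly(
        mesh=mesh,
        config=cfg,
        cut_pairs=cut_pairs,
        bite_nodes=bite_nodes,
        fixed_faces=fixed,
        plate_info=plate_info,
        region_volumes=region_volumes,
    )


def plate_material(kind, assembly: ReducedAssembly, tag: int,
                   niti_equivalent_gpa: float = 12.0):
    """Material object for one plate.

    ``kind``: 'ti' (dense Ti-6Al-4V), 'niti' (porous NiTi at its homogenized
    equivalent modulus, linearized), 'niti_sma' (homogenized-equivalent
    superelastic response, all stress-like parameters scaled by the
    equivalent/dense modulus ratio), or any material object.  In the
    membrane-equivalent plate mode the modulus is additionally scaled by
    (real thickness)/(modelled thickness).
    """
    scale = assembly.plate_info[tag]["thickness_scale"] if tag in assembly.plate_info else 1.0
    if not isinstance(kind, str):
        return kind
    if kind == "ti":
        return LinearElastic(E=112000.0 * scale, nu=0.3, sigma_y=970.0, name="Ti-6Al-4V")
    if kind == "niti":
        return LinearElastic(
            E=niti_equivalent_gpa * 1000.0 * scale, nu=0.33, sigma_y=1011.0,
            name="porous NiTi (homogenized, linearized)",
        )
    if kind == "niti_sma":
        base = builtin_material("niti_superelastic")
        f = niti_equivalent_gpa / base.E_A
        return replace(
            base,
            E_A=base.E_A * f * scale,
            E_M=base.E_M * f * scale,
            C_M=base.C_M * f * scale,
            C_A=base.C_A * f * scale,
            sigma_y=base.sigma_y * f * scale,
            name="porous NiTi (homogenized superelastic)",
        )
    raise ValueError(f"unknown plate material '{kind}'")


def _materials_for(assembly: ReducedAssembly, plate_kind) -> dict:
    mats = {
        HOST_CORT: builtin_material("cortical_host"),
        HOST_CANC: builtin_material("cancellous_host"),
        GRAFT_CORT: builtin_material("cortical_graft"),
        GRAFT_CANC: builtin_material("cancellous_graft"),
    }
    for tag in PLATE_TAGS:
        if tag in assembly.plate_info:
            mats[tag] = plate_material(plate_kind, assembly, tag)
    return mats


def porous_plate_amplification(porosity: float = 0.457, resolution: int = 16) -> float:
    """Elastic local-stress amplification of the porous plate lattice.

    Ratio of the maximum local (pore-element) von Mises stress to the
    equivalent stress of the tri-cylinder cell, from a linear homogenization
    solve.  Used to convert homogenized plate stresses to the actual stress
    carried by the lattice struts.  Dimensionless and independent of the
    solid modulus; cached per (porosity, resolution).
    """
    key = (round(porosity, 4), resolution)
    if key not in _AMP_CACHE:
        from .homogenize import equivalent_curve, local_stress_report
        from .lattice import solve_cell_for_porosity

        cell = solve_cell_for_porosity(1.0, porosity)
        r = equivalent_curve(
            cell, LinearElastic(E=37000.0, nu=0.33, name="amp probe"),
            resolution=resolution, max_strain=0.001, increments=1,
        )
        _AMP_CACHE[key] = local_stress_report(r, 0.001).amplification
    return _AMP_CACHE[key]


_AMP_CACHE: dict = {}


def apply_scenario(
    assembly: ReducedAssembly,
    scenario: LoadScenario,
    plate_kind="ti",
    pretension: float | None = None,
    porous_amplification: float | None = None,
) -> tuple[FieldResult, dict]:
    """Solve one loading scenario for one plate material.

    Returns the field result and a summary: per-region average and maximum
    element-centroid von Mises stress (plate stresses rescaled to physical
    values in the membrane-equivalent mode), mean compressive normal traction
    per host|graft interface, and the applied loads.  For porous-equivalent
    plate materials the reported plate stresses are the *actual* lattice
    stresses: homogenized stress times the local amplification factor of the
    pore cell (computed by :func:`porous_plate_amplification` unless given).
    """
    cfg = assembly.config
    mesh = assembly.mesh
    mats = _materials_for(assembly, plate_kind)
    pret = scenario.pretension if pretension is None else pretension

    dirichlet = []
    for face in assembly.fixed_faces:
        for comp in range(3):
            dirichlet.append((face, comp, 0.0))
    forces = []
    if scenario.bite:
        frac = cfg.bite_fraction if (cfg.resection and scenario.name != "healthy") else 1.0
        forces.append((assembly.bite_nodes, 2, -cfg.bite_force * frac))

    eigen = None
    if pret > 0:
        eigen = np.zeros((mesh.n_elems, 6))
        for tag, info in assembly.plate_info.items():
            m = mats[tag]
            e_mpa = m.E_A_mpa if isinstance(m, SMAParams) else m.E
            eps_star = -pret / (e_mpa * info["area_mm2"])
            eigen[info["elems_mid"], 1] = eps_star

    load = LoadCase(dirichlet=dirichlet, forces=forces, eigenstrain=eigen, n_increments=5)
    interfaces = [
        Interface(pairs=p, axis=ax, mode=scenario.interface_mode)
        for p, ax in assembly.cut_pairs
    ]

    has_sma = any(isinstance(m, SMAParams) for m in mats.values())
    if has_sma:
        if scenario.interface_mode == "contact":
            # the incremental solver couples only bonded interfaces
            interfaces = [replace(i, mode="bonded") for i in interfaces]
        res = solve_incremental_sma(mesh, mats, load, interfaces=interfaces)
    else:
        res = assemble_and_solve_linear(mesh, mats, load, interfaces=interfaces)

    porous = any(
        getattr(m, "name", "").startswith("porous") for m in mats.values()
    )
    amp = 1.0
    if porous:
        amp = (
            porous_amplification
            if porous_amplification is not None
            else porous_plate_amplification()
        )

    summary = {"scenario": scenario.name, "plate_material": str(plate_kind), "pretension_n": pret}
    for name, tag in REGIONS.items():
        elems = assembly.region_elems(tag)
        if len(elems) == 0:
            continue
        vm = res.vm[elems]
        scale = 1.0
        if tag in assembly.plate_info:
            scale = amp / assembly.plate_info[tag]["thickness_scale"]
        summary[f"avg_vm_{name}"] = float(vm.mean() * scale)
        summary[f"max_vm_{name}"] = float(vm.max() * scale)
    plate_max = [
        summary[f"max_vm_{n}"] for n, t in REGIONS.items()
        if t in assembly.plate_info and f"max_vm_{n}" in summary
    ]
    summary["max_vm_plates"] = max(plate_max) if plate_max else 0.0
    summary["avg_vm_graft"] = summary.get("avg_vm_graft_cortical", 0.0)
    summary["interface_traction_mpa"] = (
        res.interface_tractions if res.interface_tractions else []
    )
    summary["mean_interface_traction_mpa"] = (
        float(np.mean(res.interface_tractions)) if res.interface_tractions else 0.0
    )
    return res, summary


def compare_models(
    assembly: ReducedAssembly,
    scenario_names=("A", "B", "C"),
    arms=("ti", "niti"),
) -> pd.DataFrame:
    """Side-by-side comparison of the two plate materials.

    Returns one row per scenario with the raw summaries of both arms and the
    second/first-arm ratios of graft stress, host stress, interface traction
    and plate maximum stress.
    """
    rows = []
    for name in scenario_names:
        sc = SCENARIOS[name]
        summaries = {}
        for arm in arms:
            _, s = apply_scenario(assembly, sc, plate_kind=arm)
            summaries[str(arm)] = s
        a, b = summaries[str(arms[0])], summaries[str(arms[1])]

        def ratio(key):
            num, den = b.get(key, np.nan), a.get(key, np.nan)
            return num / den if den else np.inf

        rows.append(
            {
                "scenario": name,
                f"avg_vm_graft_{arms[0]}": a["avg_vm_graft_cortical"],
                f"avg_vm_graft_{arms[1]}": b["avg_vm_graft_cortical"],
                "graft_stress_ratio": ratio("avg_vm_graft_cortical"),
                "host_stress_ratio": ratio("avg_vm_host_cortical"),
                "interface_traction_ratio": ratio("mean_interface_traction_mpa"),
                f"plate_max_{arms[0]}": a["max_vm_plates"],
                f"plate_max_{arms[1]}": b["max_vm_plates"],
                "plate_max_ratio": ratio("max_vm_plates"),
            }
        )
    return pd.DataFrame(rows)
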