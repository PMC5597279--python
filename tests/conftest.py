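import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stiffmatch.materials import builtin_material

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def niti():
    return builtin_material("niti_superelastic")


@pytest.fixture(scope="session")
def ti():
    return builtin_material("ti6al4v")


def make_compression_load(mesh, a, eq_strain, n_increments=8):
    """Uniaxial-stress compression boundary conditions on a cell mesh."""
    from stiffmatch.fe import LoadCase

    bottom = mesh.face_nodes(2, 0)
    top = mesh.face_nodes(2, 1)
    cb = mesh.coords[bottom]
    centre = bottom[np.argmin((cb[:, 0] - a / 2) ** 2 + (cb[:, 1] - a / 2) ** 2)]
    corner = bottom[np.argmax(cb[:, 0])]
    return LoadCase(
        dirichlet=[
            (top, 2, -eq_strain * a),
            (bottom, 2, 0.0),
            (np.array([centre]), 0, 0.0),
            (np.array([centre]), 1, 0.0),
            (np.array([corner]), 1, 0.0),
        ],
        n_increments=n_increments,
    )


class MandibleLab:
    """Session-cached reduced-assembly solves (the expensive comparisons)."""

    def __init__(self):
        from stiffmatch.mandible import AssemblyConfig, generate_assembly

        self.assembly = generate_assembly(AssemblyConfig(spacing=(2.0, 2.0, 2.0)))
        self._cache = {}

    def summary(self, scenario_name, arm, pretension=None):
        from stiffmatch.mandible import SCENARIOS, apply_scenario

        key = (scenario_name, str(arm), pretension)
        if key not in self._cache:
            _, s = apply_scenario(
                self.assembly, SCENARIOS[scenario_name], plate_kind=arm,
                pretension=pretension,
            )
            self._cache[key] = s
        return self._cache[key]

    def result(self, scenario_name, arm, pretension=None):
        from stiffmatch.mandible import SCENARIOS, apply_scenario

        res, _ = apply_scenario(
            self.assembly, SCENARIOS[scenario_name], plate_kind=arm,
            pretension=pretension,
        )
        return res


@pytest.fixture(scope="session")
def mandible_lab():
    return MandibleLab()


@pytest.fixture(scope="session")
def design_results(niti, ti):
    """Full-resolution design runs for both alloys (shared by the acceptance
    checks: the porosity answers are the 'companion runs' of the local-stress
    checks)."""
    from stiffmatch.design import DesignSpec, solve_porosity_for_modulus

    out = {}
    for key, mat in (("niti", niti), ("ti", ti)):
        out[key] = solve_porosity_for_modulus(
            DesignSpec(target_modulus_gpa=12.0, material=mat)
        )
    return out
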