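import numpy as np
import pytest

from dualhear import field_control as fc
from dualhear import synthetic as syn
from dualhear import vibrometry as vib

N_CONDITION = 4096   # conditioning window samples (80 ms at 51.2 kHz)


@pytest.fixture(scope="session")
def template():
    return syn.make_template()


@pytest.fixture(scope="session")
def tank():
    return syn.TankModel()


@pytest.fixture(scope="session")
def ir_grid(tank):
    """Echoic impulse responses of the four-speaker tank on the 5x5 grid."""
    return syn.make_tank_irs(tank)


@pytest.fixture(scope="session")
def anechoic_grid():
    return syn.make_tank_irs(syn.TankModel(wall_reflection=0.0), echo_order=0)


@pytest.fixture(scope="session")
def centre_index(ir_grid):
    return ir_grid.position_index((0.0, 0.0))


@pytest.fixture(scope="session")
def single_left_program(ir_grid, template, centre_index):
    target = fc.TargetField.from_template(template, "single_L_pos",
                                          n_samples=N_CONDITION)
    program = fc.solve_program(ir_grid, target, centre_index)
    return target, program


@pytest.fixture(scope="session")
def scan_plan():
    return vib.plan_scan(800.0, 4, 1000.0)


@pytest.fixture(scope="session")
def phantom_masks():
    return syn.otolith_phantom_masks()


@pytest.fixture(scope="session")
def fig3e_motion(scan_plan, phantom_masks):
    """Reconstructed motion map of the tissue/otolith phantom."""
    structures = [
        syn.OscillatingStructure(phantom_masks["tissue"], 1.24, 0.0),
        syn.OscillatingStructure(phantom_masks["lapillus"], 0.95, -0.14 * np.pi),
    ]
    stack = syn.make_vibro_stack(structures, scan_plan, pixel_size_um=0.5, rng=0)
    return vib.reconstruct_motion(stack, pixel_size_um=0.5)
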