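"""Shared fixtures: small synthetic devices and hand-built grids.

PDE tests run on deliberately small devices (mm-scale chamber, a few
islets) so the whole suite stays fast; the physics being checked is
resolution- and size-independent.
"""

from __future__ import annotations

import numpy as np
import pytest

import isletvmo as vmo
from isletvmo.geometry import LabeledGrid, PortSpec
from isletvmo.synth import IsletGenParams, NetworkGenParams, default_device


@pytest.fixture(scope="session")
def small_device():
    """A compact perfusable device: ~1.5 × 0.8 mm chamber, a handful of
    islets, seeded vessel network spanning the channels."""
    shell = vmo.default_shell(chamber_width=1600.0, chamber_height=800.0)
    return default_device(
        seed=7,
        shell=shell,
        network=NetworkGenParams(target_total_length=4000.0, lattice_spacing=300.0, n_backbone=2),
        islets=IsletGenParams(gel_volume_ul=4.0 / 22.5),  # expect ~4 islets
    )


@pytest.fixture(scope="session")
def small_grid(small_device):
    return vmo.rasterize(small_device, 12.5)


@pytest.fixture(scope="session")
def small_flow(small_device, small_grid):
    return vmo.solve_flow(small_grid, small_device.ports)


def make_slab_grid(nx, ny, label, spacing=10.0, depth=200.0):
    """Uniform single-material rectangular grid (no geometry object)."""
    labels = np.full((nx, ny), label, dtype=np.int8)
    return LabeledGrid(
        spacing=spacing,
        origin=(0.0, 0.0),
        labels=labels,
        islet_id=np.full((nx, ny), -1, dtype=np.int32),
        depth=depth,
    )


def end_ports(nx, ny, spacing, head_left_mm, head_right_mm):
    """Full-width pressure ports on the left and right grid boundaries."""
    w = ny * spacing
    return [
        PortSpec("IN", (0.0, 0.0, 0.0, w), head_mm=head_left_mm),
        PortSpec("OUT", (nx * spacing, 0.0, nx * spacing, w), head_mm=head_right_mm),
    ]
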