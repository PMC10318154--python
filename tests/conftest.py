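"""Shared fixtures: a small spherical head model, sensor array, source grid
and lead field reused across beamformer and simulation tests."""

import numpy as np
import pytest

from dicsnet import (HeadModel, build_grid, compute_leadfield,
                     fibonacci_sensors)


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def sensors32():
    return fibonacci_sensors(32)


@pytest.fixture(scope="session")
def grid10(head):
    return build_grid(head, spacing=10.0)


@pytest.fixture(scope="session")
def leadfield32(head, sensors32, grid10):
    return compute_leadfield(head, sensors32, grid10)


@pytest.fixture(scope="session")
def grid_coarse(head):
    return build_grid(head, spacing=18.0)


@pytest.fixture(scope="session")
def leadfield_coarse(head, sensors32, grid_coarse):
    return compute_leadfield(head, sensors32, grid_coarse)


def make_recording(data, srate, positions):
    from dicsnet.preprocess import Recording

    n = data.shape[0]
    return Recording(data=data, srate=srate,
                     channel_labels=[f"E{i+1}" for i in range(n)],
                     sensor_positions=positions[:n])
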