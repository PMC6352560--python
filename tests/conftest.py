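"""Shared fixtures and factories for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wdpu.builder import CompositionPreset, build_chain_topology
from wdpu.generator import DensityProfile, GeneratorConfig
from wdpu.system import ParticleSystem

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_system(positions, masses=None, radii=None, charges=None, tags=None,
                chain_id=None, segment_type=None, block_type=None,
                hbond_role=None, bonds=None, angles=None, torsions=None,
                out_of_plane=None, chain_ends=None, segment_ends=None,
                segment_ends_type=None, segment_ends_chain=None,
                segment_index=None, box=None) -> ParticleSystem:
    """Assemble a ParticleSystem from whichever pieces a test cares about."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)

    def default(v, fill, dtype=float):
        if v is not None:
            return np.asarray(v)
        return np.full(n, fill, dtype=dtype)

    def empty(width):
        return np.empty((0, width), dtype=np.intp)

    return ParticleSystem(
        positions=positions,
        masses=default(masses, 1.0),
        radii=default(radii, 1.7),
        charges=default(charges, 0.0),
        tag=default(tags, "C", dtype="U6"),
        chain_id=default(chain_id, 0, dtype=np.intp),
        unit_index=np.zeros(n, dtype=np.intp),
        segment_type=default(segment_type, "PCL", dtype="U6"),
        block_type=default(block_type, "PCL", dtype="U6"),
        segment_index=default(segment_index, 0, dtype=np.intp),
        hbond_role=default(hbond_role, "none", dtype="U16"),
        bonds=bonds if bonds is not None else empty(2),
        angles=angles if angles is not None else empty(3),
        torsions=torsions if torsions is not None else empty(4),
        out_of_plane=out_of_plane if out_of_plane is not None else empty(4),
        chain_ends=chain_ends if chain_ends is not None else empty(2),
        segment_ends=segment_ends if segment_ends is not None else empty(2),
        segment_ends_type=(segment_ends_type if segment_ends_type is not None
                           else np.empty(0, "U6")),
        segment_ends_chain=(segment_ends_chain if segment_ends_chain is not None
                            else np.empty(0, np.intp)),
        box=box)


@pytest.fixture(scope="session")
def small_preset() -> CompositionPreset:
    """A reduced chain (hundreds of particles) for fast generator tests."""
    return CompositionPreset.PCL75DL25(
        particle_target=400, pcl_repeats_per_segment=2, pla_repeats_per_segment=3)


@pytest.fixture(scope="session")
def small_config(small_preset) -> GeneratorConfig:
    return GeneratorConfig(
        seed=42, n_chains=4, preset=small_preset,
        density_profile=DensityProfile(core_radius=15.0, decay_radius=35.0))


@pytest.fixture(scope="session")
def full_chain():
    """One default-size (3,070-particle) chain topology."""
    return build_chain_topology(CompositionPreset.PCL75DL25(), seed=0)
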