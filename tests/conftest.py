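"""Shared fixtures: small synthetic sections and qPCR plates.

Everything is generated at test time from fixed seeds; no data files.
"""

import numpy as np
import pytest

import fiberquant as fq
from fiberquant import synth
from fiberquant.design import generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> fq.SectionSpec:
    """A quick-to-render section: 60 fibers in a 300 px field."""
    return fq.SectionSpec(
        n_fibers=60, field_size=300, mean_fiber_radius=16, seed=11, gap_fraction=0.0
    )


@pytest.fixture(scope="session")
def small_section(small_spec):
    return fq.generate_section(small_spec)


@pytest.fixture(scope="session")
def clean_section():
    """Noiseless, blur-free, gap-free section: quantification recovers truth."""
    spec = fq.SectionSpec(
        n_fibers=60,
        field_size=300,
        mean_fiber_radius=16,
        seed=5,
        gap_fraction=0.0,
        intensity_noise_sd=0.0,
        laminin_blur_sigma=0.0,
        gfp_positive_fraction=0.5,
        probe_effect=0.5,
    )
    return fq.generate_section(spec)


@pytest.fixture(scope="session")
def gapped_section():
    """Section with 5 px boundary gaps, the gap-repair test bed."""
    spec = fq.SectionSpec(n_fibers=200, field_size=512, seed=3, gap_fraction=0.1)
    return fq.generate_section(spec)


@pytest.fixture(scope="session")
def cohort5():
    return generate_cohort(5)


@pytest.fixture(scope="session")
def noiseless_qpcr(cohort5):
    spec = synth.QpcrSpec(
        genes=synth.default_qpcr_genes(), ct_noise_sd=0.0, mouse_effect_sd=0.0, seed=2
    )
    return synth.generate_qpcr(spec, cohort5), spec
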