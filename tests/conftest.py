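import numpy as np
import pytest

from hearttube import ImageStack, SyntheticConfig, synthesize_heart


def plain_tube_config(kind, params, fractions=(0.2,) * 5, grid=(40, 60, 130),
                      spacing=(2.0, 1.0, 1.0), radius=8.0, **kwargs):
    """Noise-free, nucleus-free tube for geometry tests."""
    return SyntheticConfig(
        grid_shape=grid,
        spacing=spacing,
        centerline_kind=kind,
        centerline_params=params,
        compartment_fractions=fractions,
        tube_radius_by_compartment=(radius,) * 5,
        n_nuclei_by_compartment=(0,) * 5,
        psf_sigma=(0.0, 0.0, 0.0),
        gaussian_sd=0.0,
        poisson_scale=0.0,
        **kwargs,
    )


def ported_arc_config(radius, port_turn_fraction, grid, end_frac=0.05,
                      spacing=(2.0, 1.0, 1.0), radius_tube=8.0):
    """Arc tube whose inflow/outflow ports span exactly ``port_turn_fraction``.

    The pre-atrium and postventricle each take ``end_frac`` of the arc, so
    the interface ports (pre-atrium|atrium and ventricle|postventricle) sit
    at the endpoints of the nominal arc and the arc/chord closed forms apply
    to the measured ratio directly.
    """
    total_turn = port_turn_fraction / (1.0 - 2.0 * end_frac)
    mid = (1.0 - 2.0 * end_frac) / 3.0
    return plain_tube_config(
        "arc",
        {"radius": radius, "turn_fraction": total_turn},
        fractions=(end_frac, mid, mid, mid, end_frac),
        grid=grid,
        spacing=spacing,
        radius=radius_tube,
    )


@pytest.fixture(scope="session")
def default_heart():
    """One default 50-nucleus heart (arc tube, PSF blur, Poisson+Gaussian noise)."""
    return synthesize_heart(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def clean_heart():
    """Noise-free, blur-free default-geometry heart for exact tests."""
    cfg = SyntheticConfig(
        seed=7, psf_sigma=(0.0, 0.0, 0.0), gaussian_sd=0.0, poisson_scale=0.0
    )
    return synthesize_heart(cfg)


def make_sphere_image(shape, center, radius, spacing=(1.0, 1.0, 1.0), value=1.0):
    coords = np.indices(shape).astype(float)
    for d in range(3):
        coords[d] = (coords[d] - center[d]) * spacing[d]
    mask = np.sum(coords ** 2, axis=0) <= radius ** 2
    return ImageStack(mask.astype(float) * value, spacing)
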