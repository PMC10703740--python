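"""Shared fixtures.

Expensive physics products (256 px simulations, the 64 px paired dataset)
are session-scoped so the several tests that need them pay for them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from ctmar.artifact import SimConfig, simulate_artifact
from ctmar.attenuation import monochromatic_spectrum
from ctmar.datasets import make_paired_dataset
from ctmar.phantom import (PhantomSpec, TransducerSpec, anterior_pose,
                           insert_transducer, make_thorax_phantom,
                           make_transducer)


@pytest.fixture(scope="session")
def phantom256():
    """Default 256 px phantom with label map and body mask."""
    spec = PhantomSpec.default(256)
    ct, label = make_thorax_phantom(spec, seed=1)
    body = label > 0
    return {"spec": spec, "ct": ct, "label": label, "body": body,
            "body_interior": ndimage.binary_erosion(body, iterations=3)}


@pytest.fixture(scope="session")
def phantom256_with_probe(phantom256):
    """The same phantom with the 6 cm probe on the anterior surface."""
    spec = phantom256["spec"]
    tspec = TransducerSpec()
    overlay = make_transducer(tspec, spec.image_size, spec.pixel_spacing)
    ct_probe, metal = insert_transducer(phantom256["ct"], overlay,
                                        anterior_pose(spec, tspec),
                                        label_map=phantom256["label"])
    return {"ct": ct_probe, "metal": metal, "tspec": tspec}


@pytest.fixture(scope="session")
def identity_sim256(phantom256):
    """Artifact-free simulation limit: no metal, no noise, monochromatic."""
    cfg = SimConfig(noise=False, spectrum=monochromatic_spectrum(70.0))
    return simulate_artifact(phantom256["ct"], None, cfg)


@pytest.fixture(scope="session")
def poly_sim256(phantom256, phantom256_with_probe):
    """Full artifact case: polychromatic spectrum + Poisson + 6 cm bar."""
    cfg = SimConfig(noise=True)
    art = simulate_artifact(phantom256_with_probe["ct"],
                            phantom256_with_probe["metal"], cfg, seed=7)
    return {"art": art, "cfg": cfg}


@pytest.fixture(scope="session")
def mono_metal_sim256(phantom256, phantom256_with_probe):
    """Metal present, noise off, monochromatic: locality analysis case."""
    cfg = SimConfig(noise=False, spectrum=monochromatic_spectrum(70.0))
    art = simulate_artifact(phantom256_with_probe["ct"],
                            phantom256_with_probe["metal"], cfg)
    return {"art": art, "cfg": cfg}


@pytest.fixture(scope="session")
def dataset64():
    """30 paired 64 px patients from the full simulation chain."""
    return make_paired_dataset(30, image_size=64, seed=11)
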