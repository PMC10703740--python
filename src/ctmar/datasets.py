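"""Assembly of paired synthetic datasets: phantom -> transducer -> simulator.

One "patient" is one jittered phantom anatomy; its clean slice is CT_ref and
the simulated slice with the inserted probe is CT_art.  Seeds for anatomy,
probe pose and projection noise all derive from the dataset seed, so a
dataset is a pure function of (parameters, seed).
"""

from __future__ import annotations

import numpy as np

from .artifact import SimConfig, simulate_artifact
from .core import PairedSample
from .phantom import (PhantomSpec, TransducerSpec, anterior_pose,
                      insert_transducer, make_thorax_phantom, make_transducer)

__all__ = ["make_paired_dataset"]


def make_paired_dataset(n_patients: int, image_size: int = 64,
                        seed: int = 0,
                        sim_cfg: SimConfig | None = None,
                        phantom_spec: PhantomSpec | None = None,
                        transducer_spec: TransducerSpec | None = None,
                        pose_jitter_deg: float = 8.0,
                        ) -> list[PairedSample]:
    """Generate ``n_patients`` aligned (CT_ref, CT_art) pairs.

    The probe is placed on the anterior body surface with a small seeded
    rotation jitter per patient.  ``sim_cfg`` defaults to a view count
    scaled to the image size (720 at 512 px) with the polychromatic
    spectrum and Poisson noise active.
    """
    spec = phantom_spec or PhantomSpec.default(image_size)
    tspec = transducer_spec or TransducerSpec()
    if sim_cfg is None:
        sim_cfg = SimConfig(n_views=max(90, int(720 * image_size / 512)))
    rng = np.random.default_rng([seed, 0x64617461])

    samples = []
    for i in range(n_patients):
        pat_seed = int(rng.integers(0, 2 ** 31 - 1))
        ref, label = make_thorax_phantom(spec, seed=pat_seed)
        ref.id = f"pt{i:03d}"
        overlay = make_transducer(tspec, spec.image_size, spec.pixel_spacing)
        pose = anterior_pose(spec, tspec,
                             angle_deg=float(rng.uniform(-pose_jitter_deg,
                                                         pose_jitter_deg)))
        with_probe, metal = insert_transducer(ref, overlay, pose,
                                              label_map=label)
        art = simulate_artifact(with_probe, metal, sim_cfg,
                                seed=int(rng.integers(0, 2 ** 31 - 1)))
        art.id = f"pt{i:03d}-art"
        samples.append(PairedSample(
            ref=ref, art=art, patient_id=f"pt{i:03d}", slice_id=f"pt{i:03d}",
            provenance={"phantom_seed": pat_seed,
                        "pose_deg": pose.angle_deg,
                        "label_counts": np.bincount(label.ravel(),
                                                    minlength=5).tolist()}))
        samples[-1].provenance["label_map"] = label
    return samples
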