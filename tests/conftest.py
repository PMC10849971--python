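import numpy as np
import pytest

from embryoquant import (DiscSpec, SceneSpec, SizeFilterParams,
                         detect_compartments, make_scene)


def polar_disc_spec(center, radius=30.0, cer1_angle=90.0, tbxt_angle=None,
                    amplitude=1.0, width=30.0, marker_baseline=0.2):
    """A disc with marker baselines and optional CER1/TBXT polar domains."""
    domains = [("CER1", cer1_angle, width, amplitude)]
    if tbxt_angle is not None:
        domains.append(("TBXT", tbxt_angle, width, amplitude))
    return DiscSpec(
        centroid=center, radius=radius,
        channel_levels={"mKate": 1.0, "CER1": marker_baseline,
                        "TBXT": marker_baseline},
        polar_domains=domains,
    )


@pytest.fixture
def disc_scene():
    """One clean 50-µm disc with anti-polar CER1/TBXT domains."""
    spec = SceneSpec(
        width=160, height=160, pixel_size=1.0,
        compartments=[polar_disc_spec((80, 80), radius=50.0,
                                      cer1_angle=90.0, tbxt_angle=270.0)],
        background_level=0.0, noise_sd=0.0, seed=7,
    )
    scene, manifest = make_scene(spec)
    return scene, manifest


@pytest.fixture
def disc_record(disc_scene):
    scene, _ = disc_scene
    params = SizeFilterParams(100.0, 100.0, threshold=0.5)
    records = detect_compartments(scene, "mKate", params)
    assert len(records) == 1
    return scene, records[0]


def disc_mask(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr + 0.5 - center[0]) ** 2 + (cc + 0.5 - center[1]) ** 2 <= radius ** 2
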