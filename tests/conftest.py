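"""Shared fixtures: phantoms are generated once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import octretina as ot

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noise_free():
    """Ideal (speckle- and noise-free) phantom without ONH or vessels."""
    vol, truth = ot.make_phantom(ot.PhantomConfig(seed=1).noise_free())
    return vol, truth


@pytest.fixture(scope="session")
def noise_free_seg(noise_free):
    vol, truth = noise_free
    return ot.segment_retina(vol), truth


@pytest.fixture(scope="session")
def study():
    """One speckled study-condition phantom (vessels + ONH), seed 1."""
    vol, truth = ot.make_phantom(ot.study_config(seed=1))
    return vol, truth


@pytest.fixture(scope="session")
def study_seg(study):
    vol, truth = study
    with np.errstate(all="ignore"):
        seg = ot.segment_retina(vol)
    return seg, truth


@pytest.fixture(scope="session")
def study_suite():
    """Five seeded study phantoms with segmentations and angiography.

    Returns a list of dicts with keys vol, truth, seg, angio.
    """
    out = []
    for seed in range(1, 6):
        vol, truth = ot.make_phantom(ot.study_config(seed=seed))
        seg = ot.segment_retina(vol)
        angio = ot.motion_robust_variance(vol)
        out.append({"vol": vol, "truth": truth, "seg": seg, "angio": angio})
    return out


def vessel_dice(item) -> float:
    """Dice between the detected en-face vessel mask and phantom truth."""
    truth, angio = item["truth"], item["angio"]
    vd = truth.boundaries["vitreous_NFL"]
    od = truth.boundaries["OPL"]
    enface = ot.enface_projection(
        angio.variance, (int(vd.min()), int(od.max()) + 1)
    )
    mask = ot.vessel_mask(enface).mask
    tmask = item["truth"].vessel_mask
    return 2.0 * (mask & tmask).sum() / (mask.sum() + tmask.sum())
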