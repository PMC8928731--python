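"""Shared synthetic-scene fixtures (session-scoped: detection is the slow part)."""

import numpy as np
import pytest

from beadmetrics import (BeadSpec, SceneSpec, detect_beads,
                         render_brightfield_scene, render_fluorescence_scene)

PIXEL_SIZE_UM = 4.0


@pytest.fixture(scope="session")
def three_bead_setup():
    """Brightfield scene with three well-separated beads of known geometry."""
    spec = SceneSpec(512, 512, PIXEL_SIZE_UM, "brightfield",
                     noise_sd=0.01, seed=7)
    beads = [BeadSpec(140, 150, 560), BeadSpec(380, 160, 624),
             BeadSpec(250, 390, 700)]
    scene, truth = render_brightfield_scene(spec, beads)
    return spec, beads, scene, truth


@pytest.fixture(scope="session")
def three_bead_detections(three_bead_setup):
    _, _, scene, _ = three_bead_setup
    return detect_beads(scene)


@pytest.fixture(scope="session")
def single_bead_noiseless():
    """One clean 624-um bead, no noise: geometry oracle for edge tests."""
    spec = SceneSpec(320, 320, PIXEL_SIZE_UM, "brightfield",
                     noise_sd=0.0, seed=0)
    bead = BeadSpec(160, 160, 624)
    scene, truth = render_brightfield_scene(spec, [bead])
    return spec, bead, scene, truth


@pytest.fixture(scope="session")
def fluorescence_half_permeable():
    spec = SceneSpec(320, 320, PIXEL_SIZE_UM, "fluorescence",
                     noise_sd=0.0, background_level=0.9, seed=0)
    bead = BeadSpec(160, 160, 624, permeation_fraction=0.5)
    scene, truth = render_fluorescence_scene(spec, [bead])
    return spec, bead, scene, truth


def make_detected(bead: BeadSpec, pixel_size_um: float = PIXEL_SIZE_UM,
                  score: float = 1.0):
    """DetectedBead constructed from generator ground truth (oracle bypass
    of the detector for tests that probe measurement operations only)."""
    from beadmetrics import DetectedBead
    r_px = bead.diameter_um / 2 / pixel_size_um
    return DetectedBead(bead.center_x_px, bead.center_y_px, r_px,
                        bead.diameter_um, score)
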