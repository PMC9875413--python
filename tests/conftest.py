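"""Shared fixtures: small phantoms and exhaustion states built per session."""

import numpy as np
import pytest

from exhaustscope.imaging import RoiMask, ScanVolume
from exhaustscope.phantom import ExhaustionState, PhantomSpec, generate_phantom


def make_state(terminal: float) -> ExhaustionState:
    """An exhaustion state with a prescribed terminal-Tex fraction."""
    early = 0.9 * (1.0 - terminal)
    return ExhaustionState(
        early_tex_frac=early,
        terminal_tex_frac=terminal,
        e_t_ratio=early / terminal if terminal > 0 else float("inf"),
        pd1_mfi=800.0 + 2600.0 * terminal,
    )


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom (PET activity, CT, mask) at moderate exhaustion."""
    return generate_phantom(PhantomSpec(seed=7), make_state(0.5))


@pytest.fixture()
def small_scan():
    """A tiny deterministic PET scan with an all-foreground mask."""
    rng = np.random.default_rng(0)
    vox = rng.uniform(0.5, 2.0, size=(6, 6, 6))
    scan = ScanVolume(
        voxels=vox,
        spacing_mm=(1.0, 1.0, 1.0),
        modality="PET",
        unit="kBq/mL",
        meta={"injected_dose_MBq": 5.55, "body_weight_g": 20.0},
    )
    mask = RoiMask(voxels=np.ones((6, 6, 6), dtype=np.uint8), spacing_mm=(1.0, 1.0, 1.0))
    return scan, mask
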