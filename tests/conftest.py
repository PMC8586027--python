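import numpy as np
import pandas as pd
import pytest

from cortexpen import cortex_profile, smlm_core, synthgen


def render_two_channel(actin: pd.DataFrame, target: pd.DataFrame, pixel_size=10.0):
    """Render both channels of a cortex scene on a common grid."""
    both = pd.concat([actin, target])
    m = 4 * both["uncertainty"].max()
    extent = (
        (both["x"].min() - m, both["x"].max() + m),
        (both["y"].min() - m, both["y"].max() + m),
    )
    return {
        "actin": smlm_core.render(actin, pixel_size, extent),
        "target": smlm_core.render(target, pixel_size, extent),
    }


def measure_scene_overhang(target_depth, target_fwhm, seed, n_loc=15000):
    """Generate an SMLM cortex scene and run the full profile pipeline."""
    spec = synthgen.CortexSceneSpec(
        target_band=synthgen.BandSpec(target_depth, target_fwhm, n_loc)
    )
    actin, target, truth = synthgen.gen_smlm_cortex(spec, seed)
    images = render_two_channel(actin, target)
    result = cortex_profile.analyze_cortex(images)
    return truth, result


@pytest.fixture(scope="session")
def cortex_scene():
    """One drift-free two-channel cortex scene with a 22.7% true overhang."""
    spec = synthgen.CortexSceneSpec(
        target_band=synthgen.BandSpec(140.0, 220.0, 15000)
    )
    actin, target, truth = synthgen.gen_smlm_cortex(spec, 11)
    return spec, actin, target, truth


@pytest.fixture(scope="session")
def rendered_cortex(cortex_scene):
    _, actin, target, truth = cortex_scene
    return render_two_channel(actin, target), truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
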