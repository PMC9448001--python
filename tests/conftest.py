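import numpy as np
import pytest

import fissionlapse as fl
from fissionlapse.segmentation import build_static_mask_set


@pytest.fixture(scope="session")
def wildtype_eb1_run():
    """One analysed wild-type EB1 movie (20-s frames, 1 division), shared.

    Returns a dict with the movie, ground truth, unmixed movie, per-frame
    masks, static masks, and the scored event log.
    """
    scene, kinetics = fl.make_preset_config("wildtype", reporter="eb1",
                                            n_divisions=1)
    movie, truth = fl.simulate_movie(scene, kinetics, seed=101,
                                     frame_interval=1.0 / 3.0)
    unmixed, model = fl.unmix_movie(movie)
    g = np.asarray(unmixed.channel("reporter"))
    r = np.asarray(movie.channel("reference"))
    masks = [fl.build_mask_set(g[i], r[i]) for i in range(movie.n_frames)]
    static = build_static_mask_set(g, r)
    log = fl.score_mitotic_events(unmixed, masks)
    return {
        "movie": movie, "truth": truth, "unmixed": unmixed, "model": model,
        "masks": masks, "static_masks": [static] * movie.n_frames, "log": log,
    }


@pytest.fixture(scope="session")
def noiseless_cyclin_run():
    """Noiseless cyclin-reporter movie with one division, shared."""
    scene = fl.SceneParams(noise=fl.NoiseParams.noiseless())
    kinetics = fl.KineticParams()
    movie, truth = fl.simulate_movie(scene, kinetics, seed=7,
                                     frame_interval=2.0, n_frames=20)
    unmixed, model = fl.unmix_movie(movie)
    return {"movie": movie, "truth": truth, "unmixed": unmixed,
            "model": model, "scene": scene, "kinetics": kinetics}
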