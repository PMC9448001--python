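"""Remove chloroplast bleed-through from the reporter channel.

Per frame, the bleed ratio F is the mean green/red ratio over the top 1% of
reference pixels (pure chloroplast); the reporter image is then
CYC = (G - F*R)/k.  On a noiseless movie the recovery is exact.
"""

import numpy as np

import fissionlapse as fl

scene = fl.SceneParams(noise=fl.NoiseParams.noiseless())
movie, truth = fl.simulate_movie(scene, fl.KineticParams(), seed=0,
                                 frame_interval=3.0)
unmixed, model = fl.unmix_movie(movie, top_fraction=0.01)

print(f"true F = {truth.true_F}")
print(f"per-frame F-hat: min {model.F_per_frame.min():.6f}, "
      f"max {model.F_per_frame.max():.6f}")
totals = np.asarray(unmixed.channel("reporter")).sum(axis=(1, 2))
err = np.abs(totals / truth.true_trace - 1).max()
print(f"worst relative error of the recovered reporter trace: {err:.2e}")
# The unmixed total tracks the injected nuclear signal frame by frame;
# bleed-through (most of the raw green signal) is gone.
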