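"""Image-based path: render cells as disks, extract ROI means, compare paths.

The trace-level and image-level pipelines agree exactly on noiseless data
because ROI averaging commutes with linear unmixing.
"""

import numpy as np

import caspaseflow as cf

config = cf.PopulationConfig(n_cells=4, rng_seed=6, noise_sd=0.0)
kinetics, _ = cf.simulate_population(config)
mixing = cf.default_mixing_model()

layout = cf.disk_layout(4, frame_shape=(96, 96), radius=10)
stack, mask = cf.render_image_stack(kinetics, layout, mixing, noise_sd=0.0,
                                    seed=2, frame_shape=(96, 96),
                                    n_frames=config.n_frames)
print(f"stack shape (T, C, Y, X): {stack.shape}; ROI labels: {sorted(set(mask.ravel()) - {0})}")

roi_traces = cf.extract_roi_traces(stack, mask, config.frame_interval,
                                   channel_labels=mixing.channels)
direct = cf.render_channel_traces(kinetics, mixing, noise_sd=0.0, seed=2,
                                  n_frames=config.n_frames)
dev = np.abs(roi_traces.data - direct.data).max()
print(f"max |ROI-mean trace - direct trace| = {dev:.2e}  (numerical zero)")

abundances = cf.unmix_traces(roi_traces, mixing)
ratio = cf.normalize_trace(cf.compute_fret_ratio(abundances, cf.SENSOR_C9)[0])
profile = cf.extract_profile(ratio.norm, config.frame_interval, "c9")
print(f"cell 1 caspase-9 onset from the image path: {profile.initiation:.0f} s "
      f"(kinetic truth {kinetics[0].t_init9:.0f} s)")
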