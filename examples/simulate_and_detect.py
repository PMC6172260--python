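"""Render a synthetic synaptosome field and detect synapse candidates.

The marker channel is smoothed with a 480 nm Gaussian kernel and local
maxima above a robust median + 5*MAD threshold become candidates.
"""

import cosiquant as cq

spec = cq.SimulationSpec(n_spots=30, image_shape_px=(320, 320), seed=42)
field, truth = cq.simulate_field(spec)
config = cq.PipelineConfig()

result = cq.find_candidates(field, config)
print(f"planted spots        : {spec.n_spots}")
print(f"detected candidates  : {len(result.candidates)}")
print(f"intensity threshold  : {result.threshold_used:.1f} (a.u., smoothed)")
print(f"maxima below cut     : {result.n_rejected_by_threshold}")
# Every candidate is an initial guess for the Gaussian-fitting stage; at this
# SNR all planted synapses should be recovered with no spurious maxima.
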