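"""Per-second topic features and their one-hot normalization.

LDA compresses each second's bag of motion words into a K-simplex topic
mixture theta; the normalizer then snaps theta to a single observation
symbol — here with both the argmax ('top') rule and a k-means codebook.
"""

import numpy as np

import phaseflow as pf
from phaseflow.feature_norm import kmeans_fit, kmeans_one_hot, top_one_hot

# two-phase workflow: rightward motion, then downward motion elsewhere
script = pf.default_script(n_phases=2, cameras=1, duration_range=(8, 8),
                           fps=5, frame_size=(120, 160), seed=4)
sequences, annotation = pf.generate_phase_videos(script)
config = pf.PipelineConfig(normalizer="top", K=4, grid=pf.GridSpec(16, 12))
documents = pf.extract_documents(sequences, config)

model, thetas = pf.fit_lda(documents, K=4, seed=0)
print("alpha = 50/K =", model.alpha)
codebook = kmeans_fit(thetas, c=2, seed=0)

print("\nsecond | true phase | theta (4 topics)              | top | kmeans")
labels = annotation.to_labels()
for t in thetas:
    theta_str = " ".join(f"{x:.2f}" for x in t.theta)
    print(f"{t.second_index:6d} | {labels[t.second_index]:10d} | {theta_str} |"
          f" {top_one_hot(t).symbol:3d} | {kmeans_one_hot(t, codebook).symbol:5d}")

# Seconds of the same phase share a dominant topic, so they collapse onto
# the same observation symbol — the discrete input the phase HMM decodes.
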