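"""Pool per-residue embeddings into a global vector, with segmentation.

Long sequences are cut into segments; pooled segment vectors are
combined with length-proportional weights, which is exact for average
pooling when the embedder ignores absolute position.
"""

import numpy as np

from locforge import MockEmbedder, embed_long_sequence, embed_residues, pool_global

backend = MockEmbedder(dim=64, seed=0, max_length=100)
short = "ACDEFGHIKLMNPQRSTVWY" * 4  # 80 residues: one segment
long = "ACDEFGHIKLMNPQRSTVWY" * 15  # 300 residues: three segments

pooled = pool_global(embed_residues(short, backend))
print(f"short sequence: dim {pooled.vector.shape[0]}, {pooled.segment_count} segment")

segmented = embed_long_sequence(long, backend, max_segment_length=100)
print(f"long sequence: {segmented.segment_count} segments of <= 100 residues")

flat = MockEmbedder(dim=64, seed=0, max_length=100, positional=False)
whole = flat.embed(long).mean(axis=0)
seg = embed_long_sequence(long, flat, max_segment_length=100).vector
print(f"position-free embedder: max |segmented - whole| = {np.abs(seg - whole).max():.2e}")
# ~1e-16: length weighting makes segmentation exactly equivalent to pooling.
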