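"""Train the hybrid CNN/FC/BiLSTM network on a planted-motif corpus.

Runs the package's desk-scale learnability benchmark: 200 training and
50 held-out proteins whose compartment labels are marked by short
planted motifs, a 21x21 AAC+DPC feature image, and the 64-dim mock
embedding channel.  Takes a few seconds on one CPU.
"""

from locforge.benchmarks import run_learnability, run_overfit

learn = run_learnability(seed=0)
print(f"learnability ({learn['n_train']} train / {learn['n_val']} val, "
      f"{learn['epochs']} epochs):")
print(f"  held-out macro-F1    {learn['macro_f1']:.3f}")
print(f"  held-out macro-MCC   {learn['macro_mcc']:.3f}")
print(f"  held-out macro-AUPRC {learn['macro_auprc']:.3f}")
# macro-F1 above 0.8 shows the full image+embedding+BiLSTM stack extracts
# the planted compositional signal from raw sequences.

overfit = run_overfit(seed=0)
print(f"memorization ({overfit['n']} examples, {overfit['epochs']} epochs): "
      f"final focal loss {overfit['final_loss']:.2e}")
# a loss near zero confirms gradients flow through every layer.
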