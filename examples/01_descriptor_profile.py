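"""Compute a classical descriptor profile for one protein sequence.

The registry concatenates seven descriptor families (AAC, DPC,
autocorrelation, CTD, QSO, PAAC, APAAC) into one named vector.
"""

from locforge import DescriptorConfig, compute_descriptor_profile, sanitize_sequence

sequence = sanitize_sequence(
    "MKKRKKRKKLAADEDEDDEEGHILVVRSTWYQNPFMCAAGGHHIKLMNPQRSTVWYACDEF"
)
config = DescriptorConfig(autocorr_lag_max=10, qso_lag_max=10, paac_lambda=10)
profile = compute_descriptor_profile(sequence, config)

print(f"sequence length {len(sequence)}, descriptor count {len(profile)}")
for name in ["AAC:K", "DPC:KK", "CTD:charge:C:1", "QSO:grantham:tau:1", "PAAC:theta:1"]:
    print(f"  {name:22s} {profile[name]:.4f}")
# AAC:K is the lysine fraction; CTD:charge:C:1 the fraction of positively
# charged residues; the tau/theta terms measure sequence-order coupling.
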