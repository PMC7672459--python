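"""Quantify ChIP and pull-down enrichment from qPCR cycle numbers.

Double-delta-Ct converts the four Ct values of a ChIP-qPCR measurement
(target and PQS-negative reference, in pulled-down and input samples)
into a fold enrichment; the pull-down helper additionally calibrates
against a co-precipitated internal-control plasmid and a mutant-motif
normalizer.
"""

from quadprobe import CtQuad, ddct_enrichment, pulldown_enrichment, simulate_ct

# a locus whose chip Ct comes up 2 cycles earlier than balance -> 4-fold
quad = CtQuad(ct_chip_target=23.0, ct_chip_ref=25.0, ct_input_target=25.0, ct_input_ref=25.0)
print(f"ddCt fold enrichment: {ddct_enrichment(quad):.2f}  (efficiency 2.0)")
print(f"same quad at efficiency 1.9: {ddct_enrichment(quad, efficiency=1.9):.2f}")

# simulated round trip: construct Cts for a known fold, recover it
q = simulate_ct(true_fold=4.0, sd=0.0)
print(f"simulated quad round-trip: {ddct_enrichment(q):.2f} (truth 4.0)")

# pull-down: target/reference plasmid ratios in pulldown vs input,
# normalized to the same ratio measured for the mutant motif
fold = pulldown_enrichment(
    q_target_pulldown=8.0, q_ref_pulldown=1.0,
    q_target_input=2.0, q_ref_input=1.0,
    normalizer=0.5,
)
print(f"pull-down fold enrichment vs mutant control: {fold:.2f}")
print("\nA fold of 1 means no enrichment over the PQS-negative reference;")
print("values >1 indicate the probe captured G4 structures at the locus.")
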