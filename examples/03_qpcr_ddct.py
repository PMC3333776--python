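"""Confirm an expression ratio by comparative-Ct (ddCt) qPCR.

Simulates a Ct table with a planted 4-fold induction of a target gene,
normalized against the mdh reference, then quantifies the ratio with the
ddCt method and tests it with a condition-label permutation test.
"""

from rhizoclass import ddct_fold, generate_ct_table, permutation_ratio_test

# noise-free: the ddCt arithmetic is lossless
clean = generate_ct_table(4.0, ct_noise_sd=0.0, n_replicates=4)
print(f"noise-free table:   planted 4.0, ddCt fold {ddct_fold(clean, 'target'):.3f}")

# realistic 0.1-cycle noise across quadruplicate wells
noisy = generate_ct_table(4.0, ct_noise_sd=0.1, n_replicates=4, seed=7)
fold = ddct_fold(noisy, "target")
p = permutation_ratio_test(noisy, "target", n_permutations=2000, seed=7)
print(f"noisy table:        planted 4.0, ddCt fold {fold:.2f}, permutation p {p:.3f}")

null = generate_ct_table(1.0, ct_noise_sd=0.1, n_replicates=4, seed=8)
fold0 = ddct_fold(null, "target")
p0 = permutation_ratio_test(null, "target", n_permutations=2000, seed=8)
print(f"null table:         planted 1.0, ddCt fold {fold0:.2f}, permutation p {p0:.3f}")

print(
    "\nThe fold is 2^(-ddCt) with doubling-per-cycle efficiency; the planted\n"
    "induction is recovered and significant (4-vs-4 wells can reach p ~ 0.029),\n"
    "while the null table stays near fold 1 with a non-significant p."
)
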