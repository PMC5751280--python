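"""Estimate allele frequencies from pooled sequencing reads with an error model.

A pool of 100 individuals holding exactly one heterozygote (true minor-allele
frequency 1/200 = 0.005) is sequenced at ~120x per individual with a per-read
miscall rate of 0.1%.  The closed-form MLE p_hat = (k/n - eps)/(1 - 2 eps)
removes the error-rate inflation that the naive read fraction k/n suffers,
and the likelihood-ratio test flags the site as polymorphic.
"""

import numpy as np

from poolburden import estimate_pool_maf, lrt_polymorphism, min_detectable_cmaf

rng = np.random.default_rng(1)
eps, true_p = 0.001, 0.005
n = int(rng.poisson(100 * 120))  # one pool, 100 individuals at 120x
phi = true_p * (1 - eps) + (1 - true_p) * eps
k = int(rng.binomial(n, phi))

naive = k / n
est = lrt_polymorphism(k, n, eps)
print(f"reads: {k} minor of {n} total")
print(f"naive frequency  k/n     = {naive:.5f}")
print(f"error-corrected  p_hat   = {est.p_hat:.5f}   (true p = {true_p})")
print(f"monomorphism LRT Lambda  = {est.lam:.1f},  p = {est.p_lrt:.2e}")
print(f"assuming eps = 0 instead : p_hat = {estimate_pool_maf(k, n, 0.0):.5f}")
print()
print(f"min detectable cMAF, cohort of 500: {min_detectable_cmaf(500):.3f}")
print("The corrected estimate strips ~eps of spurious minor reads; the tiny")
print("LRT p-value rejects monomorphism despite the sequencing noise.")
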