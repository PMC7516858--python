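"""Transport a channel confirmation degree to new prevalences.

b* is a property of the test, not of the population: once estimated it
predicts the post-test probability under any prior via
P(h1|th_e1) = P(h1) / [1 - b* P(h0)].
"""

from confirmlab import predict_from_b, predict_from_c

B_STAR = 0.9  # NAT-positive, from sensitivity 0.5 / specificity 0.95

print(f"channel confirmation b* = {B_STAR}")
for prior in (0.001, 0.1, 0.25, 0.5):
    p = predict_from_b(prior, B_STAR)
    print(f"  prevalence {prior:>5}: P(infected | positive) = {p.p_h1:.3f}")

print()
print("At prevalence 0.25 the post-test probability is 0.769; the matching")
print("prediction confirmation c* = (2*0.77-1)/0.77 = 0.701 inverts back:")
print(f"  predict_from_c(0.701) = {predict_from_c(0.701).p_h1:.2f}")
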