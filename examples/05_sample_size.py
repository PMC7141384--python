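"""Sample size for estimating an event proportion to a target precision.

How many patients are needed to estimate an expected ~5.93% event
proportion to within 2.5 percentage points at 95% confidence, and how many
must be enrolled if ~15% are lost to follow-up?
"""

from news2l import sample_size_proportion

exact = sample_size_proportion(p=0.0593, margin=0.025, conf=0.95)
with_loss = sample_size_proportion(p=0.0593, margin=0.025, conf=0.95, loss=0.15)

print(f"required analysable n : {exact.n}")
print(f"enrolment with 15% loss: {with_loss.n_inflated}")
# 343 analysable patients bound the half-width of the 95% interval at 2.5
# percentage points; anticipating 15% attrition raises enrolment to 404.
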