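"""The model's closed forms at the two canonical effort levels.

Evaluates the investigation probability h(e), the false-positive rate
alpha(W, e), the probability a novel investigation yields a publishable
(positive) result, and the expected false discovery rate among published
novel positives, for a high-effort lab (e=75) and a low-effort lab (e=15)
at power W=0.8 and base rate b=0.1.
"""

from labsim import (
    expected_fdr_novel,
    false_positive_rate,
    prob_positive_novel,
    productivity_rate,
)

W, B = 0.8, 0.1
print(f"{'effort':>8} {'h(e)':>8} {'alpha':>8} {'Pr(+)':>8} {'FDR':>8}")
for e in (75.0, 15.0):
    print(
        f"{e:8.0f} {productivity_rate(e):8.3f} {false_positive_rate(W, e):8.3f}"
        f" {prob_positive_novel(B, W, e):8.3f} {expected_fdr_novel(B, W, e):8.3f}"
    )

# A low-effort lab starts 22% more investigations per step and each novel
# investigation is twice as likely to yield a publishable positive result —
# but over two-thirds of its published positives are false discoveries.
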