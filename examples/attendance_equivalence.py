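"""Equivalence and non-inferiority verdicts from published trial counts.

Builds the primary safety comparison (first-follow-up attendance) and the
secondary detection comparison (confirmed sight-threatening retinopathy
within 24 months) from arm-level counts, and applies the prespecified
margins (5% equivalence, 1.5% non-inferiority).
"""

from riskscreen.datasets import ATTENDANCE_FIRST_FOLLOWUP, STDR_24M
from riskscreen.safety import (
    Margin,
    ProportionDiff,
    equivalence_verdict,
    newcombe_diff_ci,
    noninferiority_verdict,
)

att = ATTENDANCE_FIRST_FOLLOWUP["per_protocol"]["overall"]
pd_att = ProportionDiff(*att["individualised"], *att["control"])
d, lo, hi = newcombe_diff_ci(pd_att)
verdict = equivalence_verdict((lo, hi), Margin())
print("Attendance at first follow-up (per protocol)")
print(f"  individualised {pd_att.p1:.3f}  control {pd_att.p2:.3f}")
print(f"  difference {100 * d:+.1f}% (95% CI {100 * lo:.1f}, {100 * hi:.1f})")
print(f"  verdict at +/-5% margin: {verdict.label}")

stdr = STDR_24M["per_protocol"]["overall"]
pd_stdr = ProportionDiff(*stdr["individualised"], *stdr["control"])
d, lo, hi = newcombe_diff_ci(pd_stdr)
verdict = noninferiority_verdict((lo, hi), Margin())
print("\nSTDR detection within 24 months (per protocol)")
print(f"  individualised {pd_stdr.p1:.3f}  control {pd_stdr.p2:.3f}")
print(f"  difference {100 * d:+.1f}% (95% CI {100 * lo:.1f}, {100 * hi:.1f})")
print(f"  verdict at -1.5% margin: {verdict.label}")

# A CI entirely inside the equivalence band means the arms can be used
# interchangeably for the outcome; a lower bound above -1.5% means no
# meaningful loss of detection under individualised recall.
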