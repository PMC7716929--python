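"""Screen-positive risks and recall intervals for a few participants.

Evaluates the default multi-state risk model at three covariate profiles
and shows how the 6/12/24-month risks map to a recall interval against the
2.5% threshold: the longest horizon whose cumulative risk stays below the
threshold wins.
"""

from riskscreen.model import (
    RiskProfile,
    allocate_interval,
    default_truth_model,
    screen_positive_risk,
)

model = default_truth_model()

people = [
    ("no retinopathy, well controlled",
     "R0R0", dict(age=63, duration=5, hba1c=48, sbp=128, chol=4.0)),
    ("background retinopathy one eye, average control",
     "R1R0", dict(age=63, duration=7, hba1c=51, sbp=130, chol=4.0)),
    ("background retinopathy both eyes, long duration",
     "R1R1", dict(age=55, duration=20, hba1c=85, sbp=145, chol=5.0)),
]

print(f"{'profile':<48} {'6m':>7} {'12m':>7} {'24m':>7}  recall")
for label, state, z in people:
    risks = [screen_positive_risk(model, state, z, h) for h in (6, 12, 24)]
    group = allocate_interval(RiskProfile(*risks))
    print(
        f"{label:<48} "
        + " ".join(f"{100 * r:6.2f}%" for r in risks)
        + f"  {group.interval_months} months ({group.label} risk)"
    )

# Risks are cumulative probabilities of becoming screen-positive, so they
# grow with horizon; only a person whose 24-month risk is under 2.5% is
# safe to recall at 24 months.
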