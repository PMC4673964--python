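"""Score one surveyed person: indicator scores, composite, SES class.

The subject earns 4.5x the city poverty line, holds an average-rank
job, has a postgraduate degree, owns a 150 m2 home in the second local
price quintile, and lives in a household of three.
"""

from pharmequity import EconomicAnchors, IndividualSES, score_individual

anchors = EconomicAnchors(cpl=10.0, nmw=8.0)  # currency units are arbitrary

person = IndividualSES(
    monthly_income=45.0,
    occupation_rank="average",
    education_level="master_and_above",
    tenure="owner",
    home_surface=150.0,
    price_quintile=2,
    family_size=3,
)

score = score_individual(person, anchors)
print(f"indicator scores: income {score.income_score}, occupation {score.occupation_score}, "
      f"education {score.education_score}, home {score.home_score}, family {score.family_score}")
print(f"composite SES score: {score.composite:.0f}")
print(f"SES class: {score.ses_class.value}")
print()
print("The composite is the weighted sum 30*6 + 27*3 + 20*7 + 13*5 + 10*5 = 516;")
print("on the 100-722 scale that lands in the fourth of five classes ('good').")
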