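# Default attribute/level schema for the oral-antiviral treatment choice exercise.
# Six attributes of a hypothetical chronic hepatitis B medication; each product
# in a paired-choice scenario sets every attribute to one of these levels.
attributes:
  - name: efficacy
    description: >-
      Doctors' estimate of the probability that the medicine will continue to
      work well for 5 years (long-term efficacy).
    levels: ["71 %", "85 %", "92 %"]
  - name: bone_risk
    description: >-
      Doctors' estimate of the probability of thinning of bones (bone mass
      density loss) if the medicine is taken for 5 years.
    levels: ["< 1 %", "7 %", "14 %"]
  - name: kidney_risk
    description: >-
      Doctors' estimate of the probability of kidney damage (renal toxicity)
      if the medicine is taken for 5 years.
    levels: ["< 1 %", "10 %", "20 %"]
  - name: patients_worldwide
    description: >-
      Weight of evidence (level of use): how many patients have been
      prescribed the medicine worldwide.
    levels: ["100,000", "200,000", "400,000"]
  - name: years_on_market
    description: >-
      Weight of evidence (time in market): how many years the medicine has
      been approved in the US.
    levels: ["2 years", "4 years", "6 years"]
  - name: cost
    description: >-
      Out-of-pocket cost of the medicine per month, assuming it is taken for
      at least 12 months.
    levels: ["$0", "$50", "$100", "$150"]
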