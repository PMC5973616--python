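{
  "positive": [
    "Dietary {spice} supplementation significantly reduced the severity of {disease} in treated patients.",
    "Administration of {spice} extract improved recovery from {disease}.",
    "{spice} consumption was protective and alleviated {disease} symptoms.",
    "Treatment with {spice} attenuated {disease} progression in the cohort.",
    "{spice} exhibited strong therapeutic benefit against {disease}.",
    "Supplementation with {spice} ameliorated {disease} outcomes relative to controls."
  ],
  "negative": [
    "Intake of {spice} aggravated {disease} in several subjects.",
    "{spice} exposure worsened the course of {disease}.",
    "Adverse reactions linking {spice} to {disease} were documented.",
    "High doses of {spice} exacerbated {disease} risk.",
    "{spice} triggered harmful episodes of {disease} in sensitive individuals.",
    "Consumption of {spice} provoked onset of {disease} complications."
  ],
  "neutral": [
    "This review discusses {spice} and also mentions {disease} in passing.",
    "Samples of {spice} were collected from regions where {disease} is endemic.",
    "The survey covered {spice} usage and recorded {disease} prevalence separately.",
    "{spice} was catalogued in the same database as {disease}.",
    "Participants consuming {spice} were screened before the {disease} study began.",
    "Historical records describe both {spice} cultivation and {disease} occurrence."
  ]
}
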