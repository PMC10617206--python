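{
  "_comment": "Published categorical marginals of red and processed meat consumption in Brazilian adults without private health insurance, used to calibrate the synthetic survey generator. tail_targets map a g/day threshold to P(intake >= threshold); positive_prob is P(processed intake > 0). n_records approximates half of each survey's participant count per sex.",
  "2008-2009": {
    "male": {
      "n_records": 17000,
      "red": {"tail_targets": {"70": 0.472, "280": 0.043}},
      "processed": {"positive_prob": 0.337, "tail_targets": {"150": 0.028}, "sdlog": 0.8}
    },
    "female": {
      "n_records": 17000,
      "red": {"tail_targets": {"70": 0.344, "280": 0.013}},
      "processed": {"positive_prob": 0.306, "tail_targets": {"150": 0.016}, "sdlog": 0.8}
    }
  },
  "2017-2018": {
    "male": {
      "n_records": 18850,
      "red": {"tail_targets": {"70": 0.325, "280": 0.038}},
      "processed": {"positive_prob": 0.644, "tail_targets": {"150": 0.154}, "sdlog": 0.8}
    },
    "female": {
      "n_records": 18850,
      "red": {"tail_targets": {"70": 0.226, "280": 0.017}},
      "processed": {"positive_prob": 0.604, "tail_targets": {"150": 0.081}, "sdlog": 0.8}
    }
  }
}
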