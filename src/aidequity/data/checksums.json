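{
  "survey_summary.tsv": {
    "sha256": "536343c65bbef9f0fb97705fe65be022841551a1690ebdfde3083bf71f4dbf51",
    "n_rows": 69
  },
  "wealth_description.tsv": {
    "sha256": "9133958946c0299518365224246f3e19b9723b4c070ee947b7072d4a53560351",
    "n_rows": 15
  }
}
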