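{
  "comment": "Complete-removal vs outcome contingency panels. Rows: condition yes/no; columns: seizure-free / non-seizure-free.",
  "panels": {
    "pet_complete": {"yes": [4, 6], "no": [1, 3]},
    "flaws_complete": {"yes": [1, 5], "no": [1, 4]},
    "hfo_complete": {"yes": [5, 2], "no": [0, 8]},
    "multimodal": {"yes": [5, 1], "no": [0, 9]}
  }
}
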