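{
  "emboss": {
    "n_term": 8.6,
    "c_term": 3.6,
    "side_chain": {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "H": 6.5, "K": 10.8, "R": 12.5}
  },
  "lehninger": {
    "n_term": 9.69,
    "c_term": 2.34,
    "side_chain": {"D": 3.86, "E": 4.25, "C": 8.33, "Y": 10.07, "H": 6.0, "K": 10.53, "R": 12.48}
  },
  "grimsley": {
    "n_term": 7.7,
    "c_term": 3.3,
    "side_chain": {"D": 3.5, "E": 4.2, "C": 6.8, "Y": 10.3, "H": 6.6, "K": 10.5, "R": 12.04}
  }
}
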