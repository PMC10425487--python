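{
  "description": "Hamburger-Hamilton stage vs incubation time anchors used for staging by time; stage is interpolated linearly between anchors.",
  "anchors": [
    {"incubation_h": 20, "stage": 4.0, "label": "HH4", "somites": [0, 0]},
    {"incubation_h": 24, "stage": 6.0, "label": "HH6", "somites": [0, 1]},
    {"incubation_h": 33, "stage": 10.0, "label": "HH10", "somites": [9, 11]},
    {"incubation_h": 50, "stage": 14.5, "label": "HH14-15", "somites": [22, 25]}
  ]
}
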