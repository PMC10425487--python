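{
  "description": "Per-series growth models and axial position rules for named embryo structures. Offsets are mm from the embryo top (head tip); 'anchors' rules interpolate linearly between the exposure start (t=0) and the final sampling time; 'fraction' rules place the structure at a fixed fraction of the instantaneous body length.",
  "EA": {
    "t0_incubation_h": 20.0,
    "duration_h": 30.0,
    "L0_mm": 1.04,
    "Lf_mm": 5.0,
    "sigma_L0_mm": 0.2,
    "sigma_Lf_mm": 0.5,
    "structures": {
      "head": {"rule": "anchors", "offsets_mm": [0.0, 0.0]},
      "cephalic_process": {"rule": "anchors", "offsets_mm": [0.2, 0.2]},
      "hind_head_heart": {"rule": "anchors", "offsets_mm": [0.2, 1.4]},
      "hensens_node": {"rule": "anchors", "offsets_mm": [0.2, 5.0]},
      "optic_vesicles": {"rule": "anchors", "offsets_mm": [0.1, 0.7]},
      "tail": {"rule": "fraction", "fraction": 1.0}
    }
  },
  "EB": {
    "t0_incubation_h": 24.0,
    "duration_h": 9.0,
    "L0_mm": 1.5,
    "Lf_mm": 2.9,
    "sigma_L0_mm": 0.18,
    "sigma_Lf_mm": 0.5,
    "structures": {
      "head": {"rule": "anchors", "offsets_mm": [0.0, 0.0]},
      "hind_head_heart": {"rule": "fraction", "fraction": 0.4},
      "optic_vesicles": {"rule": "fraction", "fraction": 0.15},
      "tail": {"rule": "fraction", "fraction": 1.0}
    }
  }
}
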