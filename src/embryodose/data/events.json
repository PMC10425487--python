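{
  "description": "Inductive developmental events with their exposure-time windows (hours after agar placement, series EA clock), the structure whose exposure is assessed, and the expected interference flags for the muscarinic antagonist (AT) and agonist (CCh).",
  "window_halfwidth_h": 1.0,
  "events": [
    {"label": "T0", "t_start_h": 0.0, "t_end_h": 0.0, "event": "cephalic process, body axis position", "interaction": "autonomous, maternal siamois expression", "structure": "head", "AT": "interferes", "CCh": "no"},
    {"label": "T4", "t_start_h": 4.0, "t_end_h": 4.0, "event": "prechordal plate", "interaction": "signal from notochord to endoderm", "structure": "head", "AT": "interferes", "CCh": "no"},
    {"label": "T7", "t_start_h": 7.0, "t_end_h": 7.0, "event": "cephalic fold", "interaction": "signal from prechordal plate and notochord to ectoderm", "structure": "head", "AT": "interferes", "CCh": "no"},
    {"label": "T10", "t_start_h": 10.0, "t_end_h": 10.0, "event": "neural tube closure (neural crest migration)", "interaction": "cytoskeletal movements (tubulin/actin)", "structure": "head", "AT": "interferes", "CCh": "interferes"},
    {"label": "T10", "t_start_h": 10.0, "t_end_h": 10.0, "event": "vascular area", "interaction": "mesodermal induction to endoderm", "structure": "hind_head_heart", "AT": "interferes", "CCh": "interferes"},
    {"label": "T13", "t_start_h": 13.0, "t_end_h": 13.0, "event": "optic vesicles", "interaction": "Pax genes, inductive messages between neural tube and ectoderm", "structure": "optic_vesicles", "AT": "interferes", "CCh": "interferes"},
    {"label": "T13", "t_start_h": 13.0, "t_end_h": 13.0, "event": "brain pattern specification", "interaction": "Otx, Emx homeobox genes", "structure": "head", "AT": "interferes", "CCh": "no"},
    {"label": "T10-T13", "t_start_h": 10.0, "t_end_h": 13.0, "event": "architecture of neural tube basal plate (motor neurons)", "interaction": "induction by contact from notochord to neurectoderm", "structure": "head", "AT": "interferes", "CCh": "no"},
    {"label": "T13-T15", "t_start_h": 13.0, "t_end_h": 15.0, "event": "heart formation", "interaction": "Hedgehog and RAS pathways", "structure": "hind_head_heart", "AT": "interferes", "CCh": "no"}
  ]
}
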