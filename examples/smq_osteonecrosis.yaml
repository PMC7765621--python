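# Preferred terms of the osteonecrosis standardised MedDRA query
- osteonecrosis of the jaw
- osteonecrosis
- osteomyelitis
- atypical femoral fracture
- bone pain
- pain in jaw
- jaw abscess
- osteitis
- tooth abscess
- bacterial osteomyelitis
- osteonecrosis of external auditory canal
- groin pain
- alveolar osteitis
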