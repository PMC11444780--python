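journal,categorized,rationale
PNAS,yes,statistical
PNAS,yes,statistical
PNAS,yes,statistical
PNAS,no,
PNAS,no,
PNAS,no,
PNAS,no,
PNAS,no,
PNAS,no,
PNAS,no,
PNAS,no,
PNAS,no,
Ecology,yes,statistical
Ecology,yes,statistical
Ecology,no,
Ecology,no,
Ecology,no,
Ecology,no,
Ecology,no,
Ecology,no,
Ecology,no,
Ecology,no,
Ecology,no,
Ecology,no,
Evolution,yes,statistical
Evolution,yes,statistical
Evolution,no,
Evolution,no,
Evolution,no,
Evolution,no,
Evolution,no,
Evolution,no,
Evolution,no,
Evolution,no,
Evolution,no,
Evolution,no,
J. Exp. Biol.,yes,statistical
J. Exp. Biol.,yes,statistical
J. Exp. Biol.,yes,statistical
J. Exp. Biol.,yes,biological
J. Exp. Biol.,no,
J. Exp. Biol.,no,
J. Exp. Biol.,no,
J. Exp. Biol.,no,
J. Exp. Biol.,no,
J. Exp. Biol.,no,
J. Exp. Biol.,no,
J. Exp. Biol.,no,
Behavioral Ecology,yes,biological
Behavioral Ecology,yes,biological
Behavioral Ecology,yes,biological
Behavioral Ecology,yes,precedent
Behavioral Ecology,yes,precedent
Behavioral Ecology,no,
Behavioral Ecology,no,
Behavioral Ecology,no,
Behavioral Ecology,no,
Behavioral Ecology,no,
Behavioral Ecology,no,
Behavioral Ecology,no,
Animal Behaviour,yes,precedent
Animal Behaviour,yes,arbitrary
Animal Behaviour,yes,arbitrary
Animal Behaviour,yes,none
Animal Behaviour,yes,none
Animal Behaviour,yes,none
Animal Behaviour,no,
Animal Behaviour,no,
Animal Behaviour,no,
Animal Behaviour,no,
Animal Behaviour,no,
Animal Behaviour,no,
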