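# Default cleavage specificity rules for the simulated gastrointestinal
# digestion. Rules are data: edit or override via --enzyme-config without
# touching code. "p1" residues are cut on their carboxyl side unless the
# following residue is in "p1prime_blocked".
enzymes:
  - id: pepsin
    name: pepsin (pH > 2)
    ec_number: 3.4.23.1
    rules:
      - p1: [F, L]
        p1prime_blocked: []
  - id: trypsin
    name: trypsin
    ec_number: 3.4.21.4
    rules:
      - p1: [K, R]
        p1prime_blocked: [P]
  - id: chymotrypsin
    name: chymotrypsin
    ec_number: 3.4.21.1
    rules:
      - p1: [F, Y, W]
        p1prime_blocked: [P]
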