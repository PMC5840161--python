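{
  "description": "Key strychnine-binding positions of human bitter taste receptors T2R10 and T2R46 (Ballesteros-Weinstein numbering) with ordered substitution-effect rules from published site-directed mutagenesis (Born et al. 2013; Brockhoff et al. 2010; Sandal et al. 2015; Lossow et al. 2016). Rules are matched first to last; a substitution matching no rule has unknown effect. Property-class rules encode the qualitative statements of those studies (charge requirements, steric/hydrophobicity constraints).",
  "entries": [
    {"bw": "3.29", "mode": "R10", "key": "S", "criticality": "supporting", "rules": []},
    {"bw": "3.32", "mode": "R10", "key": "W", "criticality": "supporting", "rules": []},
    {"bw": "3.33", "mode": "R10", "key": "V", "criticality": "supporting", "rules": []},
    {"bw": "3.36", "mode": "R10", "key": "N", "criticality": "supporting", "rules": []},
    {"bw": "3.37", "mode": "R10", "key": "Q", "criticality": "critical", "rules": [
      {"sub": "A", "effect": "abolished", "source": "Born2013 Q93A complete loss"},
      {"sub": "charge:pos", "effect": "abolished", "source": "inferred: charge introduction at a loss-critical position"},
      {"sub": "charge:neg", "effect": "abolished", "source": "inferred: charge introduction at a loss-critical position"}
    ]},
    {"bw": "5.39", "mode": "R10", "key": "K", "criticality": "supporting", "rules": []},
    {"bw": "5.40", "mode": "R10", "key": "Q", "criticality": "supporting", "rules": [
      {"sub": "charge:pos", "effect": "reduced", "source": "Born2013: position relevant for activation"}
    ]},
    {"bw": "5.42", "mode": "R10", "key": "L", "criticality": "supporting", "rules": []},
    {"bw": "5.43", "mode": "R10", "key": "L", "criticality": "supporting", "rules": [
      {"sub": "volume:large", "effect": "abolished", "source": "Born2013: position relevant; bulky replacement"}
    ]},
    {"bw": "6.51", "mode": "R10", "key": "Y", "criticality": "supporting", "rules": []},
    {"bw": "7.39", "mode": "R10", "key": "M", "criticality": "critical", "rules": [
      {"sub": "A", "effect": "abolished", "source": "Born2013 M263A complete loss"},
      {"sub": "E", "effect": "abolished", "source": "Born2013 M263E complete loss"},
      {"sub": "L", "effect": "abolished", "source": "Lossow2016: rodent M263L orthologs not activated"},
      {"sub": "charge:neg", "effect": "abolished", "source": "inferred from M263E"},
      {"sub": "charge:pos", "effect": "abolished", "source": "inferred: charge introduction"}
    ]},
    {"bw": "7.42", "mode": "R10", "key": "T", "criticality": "supporting", "rules": [
      {"sub": "charge:pos", "effect": "abolished", "source": "inferred: charged bulky replacement at a sterically constrained position"}
    ]},

    {"bw": "2.61", "mode": "R46", "key": "W", "criticality": "supporting", "rules": []},
    {"bw": "2.65", "mode": "R46", "key": "E", "criticality": "supporting", "rules": [
      {"sub": "V", "effect": "tolerated", "source": "Brockhoff2010 E70V largely unaltered"}
    ]},
    {"bw": "2.66", "mode": "R46", "key": "L", "criticality": "supporting", "rules": []},
    {"bw": "3.25", "mode": "R46", "key": "I", "criticality": "supporting", "rules": [
      {"sub": "T", "effect": "reduced", "source": "Brockhoff2010 I82T decreased response"}
    ]},
    {"bw": "3.32", "mode": "R46", "key": "W", "criticality": "supporting", "rules": []},
    {"bw": "3.36", "mode": "R46", "key": "N", "criticality": "supporting", "rules": [
      {"sub": "G", "effect": "reduced", "source": "Brockhoff2010 N92G decreased response"},
      {"sub": "S", "effect": "reduced", "source": "inferred: gorilla N92S possibly reduced"}
    ]},
    {"bw": "4.65", "mode": "R46", "key": "N", "criticality": "supporting", "rules": []},
    {"bw": "ECL2", "mode": "R46", "key": "N", "criticality": "supporting", "rules": []},
    {"bw": "5.39", "mode": "R46", "key": "N", "criticality": "supporting", "rules": [
      {"sub": "D", "effect": "reduced", "source": "Brockhoff2010 N176D decreased response"}
    ]},
    {"bw": "5.42", "mode": "R46", "key": "V", "criticality": "supporting", "rules": []},
    {"bw": "6.51", "mode": "R46", "key": "Y", "criticality": "supporting", "rules": [
      {"sub": "F", "effect": "reduced", "source": "Brockhoff2010 Y241F reduced maximum activation"},
      {"sub": "S", "effect": "tolerated", "source": "Sandal2015 Y241S higher activation"},
      {"sub": "H", "effect": "unknown", "source": "may hydrogen-bond; untested"}
    ]},
    {"bw": "6.63", "mode": "R46", "key": "E", "criticality": "supporting", "rules": [
      {"sub": "G", "effect": "reduced", "source": "Brockhoff2010 E253G decreased response"},
      {"sub": "K", "effect": "reduced", "source": "inferred: bonobo E253K possibly reduced"}
    ]},
    {"bw": "7.39", "mode": "R46", "key": "E", "criticality": "critical", "rules": [
      {"sub": "D", "effect": "reduced", "source": "Brockhoff2010 E265D modest decrease"},
      {"sub": "Q", "effect": "reduced", "source": "Brockhoff2010 E265Q ~100-fold reduced sensitivity"},
      {"sub": "K", "effect": "abolished", "source": "Brockhoff2010 E265K nearly abolished"},
      {"sub": "charge:pos", "effect": "abolished", "source": "inferred from E265K: positive charge incompatible with the salt bridge"},
      {"sub": "hydropathy:hydrophobic", "effect": "abolished", "source": "inferred: loss of the negative charge required for the salt bridge"}
    ]},
    {"bw": "7.42", "mode": "R46", "key": "A", "criticality": "critical", "rules": [
      {"sub": "G", "effect": "reduced", "source": "Brockhoff2010 A268G slight decrease"},
      {"sub": "T", "effect": "reduced", "source": "inferred: A268T steric hindrance"},
      {"sub": "I", "effect": "reduced", "source": "inferred: A268I steric hindrance"},
      {"sub": "R", "effect": "abolished", "source": "Brockhoff2010 A268R nearly abolished"},
      {"sub": "volume:large", "effect": "abolished", "source": "inferred: no long side chains tolerated"}
    ]},
    {"bw": "7.43", "mode": "R46", "key": "F", "criticality": "critical", "rules": [
      {"sub": "N", "effect": "abolished", "source": "Brockhoff2010 F269N almost complete loss"},
      {"sub": "hydropathy:hydrophilic", "effect": "abolished", "source": "inferred: hydrophobicity at 7.43 is fundamental"},
      {"sub": "hydropathy:hydrophobic", "effect": "reduced", "source": "inferred: hydrophobicity preserved, geometry altered"}
    ]}
  ]
}
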