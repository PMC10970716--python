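name: migraine
notes:
- Effects of excluding a brand-name migraine preventive, counts in thousands, as
  printed.
- Row label printed as 'Qulipta (ubrogepant)'; Qulipta is atogepant (ubrogepant
  is Ubrelvy). Reproduced with the corrected generic in the scenario file.
cells:
- formulary: CVS
  medication: Emgality
  column: affected
  low: '858'
  high: '1050'
- formulary: CVS
  medication: Emgality
  column: discontinue
  low: '77'
  high: '200'
- formulary: CVS
  medication: Emgality
  column: adverse_events
  low: '429'
  high: '525'
- formulary: CVS
  medication: Aimovig
  column: affected
  low: '745'
  high: '911'
- formulary: CVS
  medication: Aimovig
  column: discontinue
  low: '67'
  high: '173'
- formulary: CVS
  medication: Aimovig
  column: adverse_events
  low: '373'
  high: '455'
- formulary: CVS
  medication: Ajovy
  column: affected
  low: '413'
  high: '506'
- formulary: CVS
  medication: Ajovy
  column: discontinue
  low: '37'
  high: '96'
- formulary: CVS
  medication: Ajovy
  column: adverse_events
  low: '207'
  high: '253'
- formulary: CVS
  medication: Vyepti
  column: affected
  low: '0.8'
  high: '1'
- formulary: CVS
  medication: Vyepti
  column: discontinue
  low: '0.07'
  high: '0.2'
- formulary: CVS
  medication: Vyepti
  column: adverse_events
  low: '0.4'
  high: '0.5'
- formulary: CVS
  medication: Nurtec
  column: affected
  low: '1612'
  high: '1971'
- formulary: CVS
  medication: Nurtec
  column: discontinue
  low: '145'
  high: '374'
- formulary: CVS
  medication: Nurtec
  column: adverse_events
  low: '806'
  high: '986'
- formulary: CVS
  medication: Qulipta
  column: affected
  low: '406'
  high: '496'
- formulary: CVS
  medication: Qulipta
  column: discontinue
  low: '37'
  high: '94'
- formulary: CVS
  medication: Qulipta
  column: adverse_events
  low: '203'
  high: '248'
- formulary: ESI
  medication: Emgality
  column: affected
  low: '625'
  high: '764'
- formulary: ESI
  medication: Emgality
  column: discontinue
  low: '56'
  high: '145'
- formulary: ESI
  medication: Emgality
  column: adverse_events
  low: '312'
  high: '382'
- formulary: ESI
  medication: Aimovig
  column: affected
  low: '542'
  high: '662'
- formulary: ESI
  medication: Aimovig
  column: discontinue
  low: '49'
  high: '103'
  erratum:
    bound: high
    note: printed 103; 19% of the printed affected high (662) is ~126
- formulary: ESI
  medication: Aimovig
  column: adverse_events
  low: '271'
  high: '331'
- formulary: ESI
  medication: Ajovy
  column: affected
  low: '301'
  high: '368'
- formulary: ESI
  medication: Ajovy
  column: discontinue
  low: '27'
  high: '70'
- formulary: ESI
  medication: Ajovy
  column: adverse_events
  low: '150'
  high: '184'
- formulary: ESI
  medication: Vyepti
  column: affected
  low: '0.6'
  high: '0.7'
- formulary: ESI
  medication: Vyepti
  column: discontinue
  low: '0.05'
  high: '0.14'
- formulary: ESI
  medication: Vyepti
  column: adverse_events
  low: '0.3'
  high: '0.4'
- formulary: ESI
  medication: Nurtec
  column: affected
  low: '1172'
  high: '1433'
- formulary: ESI
  medication: Nurtec
  column: discontinue
  low: '106'
  high: '272'
- formulary: ESI
  medication: Nurtec
  column: adverse_events
  low: '586'
  high: '717'
- formulary: ESI
  medication: Qulipta
  column: affected
  low: '295'
  high: '361'
- formulary: ESI
  medication: Qulipta
  column: discontinue
  low: '27'
  high: '69'
- formulary: ESI
  medication: Qulipta
  column: adverse_events
  low: '148'
  high: '180'
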