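name: anticoagulants
notes:
- Effects of excluding a brand-name anticoagulant, counts in thousands, as printed;
  dashes in the source mix hyphens and en-dashes.
- The source narrative attributes adverse-event maxima of 422 000 and 580 000 to
  CVS and ESI respectively, swapping the labels relative to this table (CVS 580,
  ESI 422).
cells:
- formulary: CVS
  medication: Eliquis
  column: affected
  low: '734'
  high: '1784'
- formulary: CVS
  medication: Eliquis
  column: discontinue
  low: '125'
  high: '535'
- formulary: CVS
  medication: Eliquis
  column: adverse_events
  low: '68'
  high: '580'
- formulary: CVS
  medication: Xarelto
  column: affected
  low: '317'
  high: '771'
- formulary: CVS
  medication: Xarelto
  column: discontinue
  low: '54'
  high: '231'
- formulary: CVS
  medication: Xarelto
  column: adverse_events
  low: '30'
  high: '251'
- formulary: CVS
  medication: Pradaxa
  column: affected
  low: '14'
  high: '34'
- formulary: CVS
  medication: Pradaxa
  column: discontinue
  low: '2.3'
  high: '10'
- formulary: CVS
  medication: Pradaxa
  column: adverse_events
  low: '1.3'
  high: '11'
- formulary: CVS
  medication: Savaysa
  column: affected
  low: '0.6'
  high: '1.5'
- formulary: CVS
  medication: Savaysa
  column: discontinue
  low: '0.1'
  high: '0.5'
- formulary: CVS
  medication: Savaysa
  column: adverse_events
  low: '0.06'
  high: '0.5'
- formulary: ESI
  medication: Eliquis
  column: affected
  low: '534'
  high: '1298'
- formulary: ESI
  medication: Eliquis
  column: discontinue
  low: '91'
  high: '389'
- formulary: ESI
  medication: Eliquis
  column: adverse_events
  low: '50'
  high: '422'
- formulary: ESI
  medication: Xarelto
  column: affected
  low: '231'
  high: '561'
- formulary: ESI
  medication: Xarelto
  column: discontinue
  low: '39'
  high: '168'
- formulary: ESI
  medication: Xarelto
  column: adverse_events
  low: '21'
  high: '182'
- formulary: ESI
  medication: Pradaxa
  column: affected
  low: '10'
  high: '25'
- formulary: ESI
  medication: Pradaxa
  column: discontinue
  low: '1.7'
  high: '7.4'
- formulary: ESI
  medication: Pradaxa
  column: adverse_events
  low: '0.9'
  high: '8.0'
- formulary: ESI
  medication: Savaysa
  column: affected
  low: '0.4'
  high: '1.1'
- formulary: ESI
  medication: Savaysa
  column: discontinue
  low: '0.08'
  high: '0.3'
- formulary: ESI
  medication: Savaysa
  column: adverse_events
  low: '0.04'
  high: '0.4'
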