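# Variety-specific sorption fitting coefficients for the absolute-water-
# potential formula.  These are PLACEHOLDER sets chosen only to give a
# well-behaved, monotone-in-temperature surface over the operating range;
# they are NOT fitted to sorption data.  Supply fitted values for
# production use.
wheat:
  A1: 3.0
  A2: 5.0
  B1: 14.5
  B2: 12.0
  D: 1.2
  verified: false
corn:
  A1: 3.5
  A2: 5.5
  B1: 16.0
  B2: 13.5
  D: 1.1
  verified: false
rice:
  A1: 3.2
  A2: 5.2
  B1: 15.0
  B2: 12.8
  D: 1.15
  verified: false
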