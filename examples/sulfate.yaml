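# Na2SO4-NaHCO3 reactor: 300-day ramp (mean OLR 0.39 g-COD/L/d)
scenario: Na2SO4_NaHCO3
schedule:
  srt: 40
  feed_cod: 158
  sulfate_feed: 0.245   # kmol-SO4 per m3 of feed concentrate
  segments:
    - [0, 90, 0.2]
    - [90, 160, 0.3]
    - [160, 220, 0.4]
    - [220, 270, 0.6]
    - [270, 300, 0.8]
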