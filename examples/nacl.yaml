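# NaCl-salinity reactor: 480-day staircase at SRT 40 d, feed 158 g-COD/L
scenario: NaCl
schedule:
  srt: 40
  feed_cod: 158
  sulfate_feed: 0.0
  segments:
    - [0, 100, 0.58]
    - [100, 180, 0.8]
    - [180, 230, 1.0]
    - [230, 260, 1.2]
    - [260, 289, 1.5]
    - [289, 320, 0.0]   # feeding pause after the propionate excursion
    - [320, 330, 0.8]
    - [330, 480, 0.75]
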