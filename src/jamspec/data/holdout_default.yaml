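# Default concentration hold-out map: per cultivar, which sugar levels (% w/w)
# are reserved for the test and validation folds. 14 test + 12 val of 88 cells
# (~15.9% / ~13.6%; 70.5% train), deterministic rotating pattern.
aport:
  test:
  - 25.0
  - 50.0
  val:
  - 30.0
  - 55.0
gala:
  test:
  - 35.0
  - 60.0
  val:
  - 40.0
  - 65.0
golden:
  test:
  - 45.0
  - 70.0
  val:
  - 50.0
  - 75.0
granny:
  test:
  - 55.0
  - 25.0
  val:
  - 60.0
  - 30.0
idared:
  test:
  - 65.0
  - 35.0
  val:
  - 70.0
prince:
  test:
  - 75.0
  - 45.0
  val:
  - 25.0
simirenko:
  test:
  - 30.0
  val:
  - 35.0
starcrimson:
  test:
  - 40.0
  val:
  - 45.0
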