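{
 "markers": [
  "MK1",
  "MK2"
 ],
 "relatives": [
  "RL1",
  "RL2"
 ],
 "similarities": [
  0.9686978024277981,
  0.9519439219876027
 ],
 "replaced": [
  true,
  false
 ]
}
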