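scenario_id: 3
version: '1'
l_model:
  a0: -1.9695879985727196
  aU: 1.5820945737966445
a_model:
  b0: -0.6250442777716294
  bL: 1.3947598307719056
  bC: 0.2280830875915389
  bU: 0.42642346061942527
ya_model:
  g0: 25.240655175079652
  gA: 4.04
  gC: -0.10047701611485362
  gU: -1.5115697927546456
  sigma: 1.9830332566185787
yb_model:
  h0: 0.7371097628256477
  hA: 1.273251510586102
  hC: -0.03063006329291178
  hU: -0.5984824006932854
yc_model:
  lambda0: 0.1
  kA: -0.863812305619619
  kC: 0.024315146155150007
  kU: 0.19759920699675582
  tau_cens: 21.27718885458624
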