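scenario_id: 1
version: '1'
l_model:
  a0: -1.5430436857478518
  aU: 0.7409173421395885
a_model:
  b0: -0.3111901279890512
  bL: 1.21421949641829
  bC: 0.21814661803568702
  bU: 0.0
ya_model:
  g0: 24.869126518330045
  gA: 3.99
  gC: -0.10026457486364711
  gU: -0.5095773630445555
  sigma: 2.0064378377024057
yb_model:
  h0: 0.8038719862803902
  hA: 1.2501047221462243
  hC: -0.0333063753669097
  hU: -0.2985562052602662
yc_model:
  lambda0: 0.1
  kA: -0.8512044645512995
  kC: 0.025195474147846918
  kU: 0.10783610320270043
  tau_cens: 21.726531006273632
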