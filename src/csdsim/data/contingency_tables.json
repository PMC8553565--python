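{
  "fig1c": {
    "labels": ["neocortex_hm1a", "neocortex_control"],
    "counts": [[16, 71], [0, 17]],
    "flag": "printed adjusted p (0.04) depends on an unstated Bonferroni comparison count; raw pairwise p = 0.034"
  },
  "fig3d": {
    "labels": ["vgat_chr2", "wt", "vgat_cre", "chr2_lox"],
    "counts": [[11, 13], [0, 14], [0, 10], [0, 10]],
    "flag": "printed p (7e-5) matches the pairwise 2x2 test vs an n=10 control group, not the overall r x 2 exact test"
  },
  "fig3e": {
    "labels": ["pv_chr2", "pv_cre"],
    "counts": [[4, 14], [0, 15]]
  },
  "fig6d": {
    "labels": ["control", "kryptofix"],
    "counts": [[7, 10], [1, 8]]
  },
  "fig7a": {
    "labels": ["control", "vu0240551", "vu0463271", "isoguvacine", "vu0463271_isoguvacine"],
    "counts": [[39, 39], [12, 12], [17, 20], [11, 11], [9, 10]]
  },
  "fig7d": {
    "labels": ["control", "ttx", "gabazine", "cpp_cnqx", "gabazine_cpp_cnqx", "cadmium"],
    "counts": [[39, 39], [0, 13], [0, 6], [16, 16], [9, 10], [10, 10]],
    "flag": "legend lists Gabazine 0% (n=6) although the text reports gabazine did not change the success rate; packaged verbatim, overall printed p (4e-14) not reproduced by any standard convention"
  },
  "fig9c": {
    "labels": ["vgat_chr2", "control"],
    "counts": [[5, 10], [0, 13]]
  }
}
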