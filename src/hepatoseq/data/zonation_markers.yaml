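# Liver lobule zonation markers: pericentral (central vein), periportal
# (portal vein), and non-zonated controls.
pericentral: [Cyp2e1, Gsta3, Cyp27a1, Mup17]
periportal: [Alb, Cyp2f2, Asl, Gls2]
non_zonated: [Hnf4a, Ces3a, Hamp, Cyp3a25]
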