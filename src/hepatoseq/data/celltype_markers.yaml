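# Marker panels used to annotate graph clusters with liver cell types.
hepatocyte: [Cyp27a1, Ppara, Pck1]
hepatobiliary: [Sspn, Cmss1, Epcam]
endothelial: [Plekhg1, Stab2, Ptprb]
apc: [Clec4f, Cd5l, Slc40a1]
lymphocyte: [Bcl2, Skap1, Gata3]
stellate: [Reln, Ecm1, Ldb2]
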