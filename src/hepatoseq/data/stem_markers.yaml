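# Liver stem/progenitor cell marker panel for binary co-expression analysis.
stem_markers: [Icam1, Afp, Sox9, Epcam, Axin2, Tbx3, Itga6, Tert, Lgr5, Notch2]
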