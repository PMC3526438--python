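(a_1[&kind=gene_leaf,loc=1],((a_2[&kind=gene_leaf,loc=2],a_3[&kind=gene_leaf,loc=3])[&kind=speciation,loc=2+3],(b_2[&kind=gene_leaf,loc=2],b_3[&kind=gene_leaf,loc=3])[&kind=speciation,loc=2+3])[&kind=duplication,loc=2+3,retainer=0])[&kind=speciation,loc=1+2+3];
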