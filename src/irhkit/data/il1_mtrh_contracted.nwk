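(((M1[&kind=gene_leaf,loc=Mouse],Rt1[&kind=gene_leaf,loc=Rat])[&kind=speciation,loc=Mouse+Rat],(Rb1[&kind=gene_leaf,loc=Rabbit],(H1[&kind=gene_leaf,loc=Human],(P1[&kind=gene_leaf,loc=Pig],((LOSS[&kind=loss_leaf,loc=Sheep],B1[&kind=gene_leaf,loc=Bovine])[&kind=speciation,loc=Bovine+Sheep],(S4[&kind=gene_leaf,loc=Sheep],B4[&kind=gene_leaf,loc=Bovine])[&kind=speciation,loc=Bovine+Sheep])[&kind=duplication,loc=Bovine+Sheep,retainer=0])[&kind=speciation,loc=Bovine+Pig+Sheep])[&kind=speciation,loc=Bovine+Human+Pig+Sheep])[&kind=speciation,loc=Bovine+Human+Pig+Rabbit+Sheep])[&kind=speciation,loc=Bovine+Human+Mouse+Pig+Rabbit+Rat+Sheep],(((M2[&kind=gene_leaf,loc=Mouse],Rt2[&kind=gene_leaf,loc=Rat])[&kind=speciation,loc=Mouse+Rat],(LOSS[&kind=loss_leaf,loc=Rabbit],(H2[&kind=gene_leaf,loc=Human],LOSS[&kind=loss_leaf,loc=Bovine+Pig+Sheep])[&kind=speciation,loc=Bovine+Human+Pig+Sheep])[&kind=speciation,loc=Bovine+Human+Pig+Rabbit+Sheep])[&kind=speciation,loc=Bovine+Human+Mouse+Pig+Rabbit+Rat+Sheep],((M3[&kind=gene_leaf,loc=Mouse],LOSS[&kind=loss_leaf,loc=Rat])[&kind=speciation,loc=Mouse+Rat],(LOSS[&kind=loss_leaf,loc=Rabbit],(H3[&kind=gene_leaf,loc=Human],LOSS[&kind=loss_leaf,loc=Bovine+Pig+Sheep])[&kind=speciation,loc=Bovine+Human+Pig+Sheep])[&kind=speciation,loc=Bovine+Human+Pig+Rabbit+Sheep])[&kind=speciation,loc=Bovine+Human+Mouse+Pig+Rabbit+Rat+Sheep])[&kind=duplication,loc=Bovine+Human+Mouse+Pig+Rabbit+Rat+Sheep,retainer=0])[&kind=duplication,loc=Bovine+Human+Mouse+Pig+Rabbit+Rat+Sheep,retainer=0];
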