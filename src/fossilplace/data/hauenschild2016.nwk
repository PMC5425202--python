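[ Backbone over the 24 sampled extant Rhamnaceae genera, consistent with the two-marker (trnL-trnF + ITS) genus-level phylogeny of Hauenschild et al. 2016. Approximate transcription: tribe composition follows the published classification; within-tribe and backbone resolution reconstructed from figure captions, not from the original figure file. Topology only; no branch lengths. ]
((Ampelozizyphus,Bathiorhamnus),((Ventilago,(Berchemia,((Rhamnus,Frangula),(Sageretia,(Scutia,(Condalia,(Karwinskia,(Krugiodendron,Reynosia)))))))),((Gouania,Helinus),((Hovenia,(Sarcomphalus,(Paliurus,Ziziphus))),(Ceanothus,(Pomaderris,((Colletia,Discaria),(Phylica,Noltea))))))));
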