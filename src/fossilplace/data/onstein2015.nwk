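[ Backbone over the 24 sampled extant Rhamnaceae genera, consistent with the seven-marker phylogeny of Onstein et al. 2015. Approximate transcription: tribe composition follows the published classification; within-tribe and backbone resolution reconstructed from figure captions, not from the original figure file. Topology only; no branch lengths. ]
((Ventilago,((Rhamnus,Frangula),((Berchemia,Sageretia),(Scutia,(Condalia,(Karwinskia,(Krugiodendron,Reynosia))))))),((Ampelozizyphus,Bathiorhamnus),((Sarcomphalus,(Hovenia,(Paliurus,Ziziphus))),((Gouania,Helinus),(Ceanothus,(Pomaderris,((Colletia,Discaria),(Phylica,Noltea))))))));
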