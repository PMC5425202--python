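{
 "source": "Hauenschild2016",
 "provenance": "approximate transcription; tribe composition from the published classification, resolution reconstructed from figure captions",
 "backbone_taxa": [
  "Ampelozizyphus",
  "Bathiorhamnus",
  "Berchemia",
  "Ceanothus",
  "Colletia",
  "Condalia",
  "Discaria",
  "Frangula",
  "Gouania",
  "Helinus",
  "Hovenia",
  "Karwinskia",
  "Krugiodendron",
  "Noltea",
  "Paliurus",
  "Phylica",
  "Pomaderris",
  "Reynosia",
  "Rhamnus",
  "Sageretia",
  "Sarcomphalus",
  "Scutia",
  "Ventilago",
  "Ziziphus"
 ],
 "floating_taxa": [
  "Notiantha"
 ],
 "clades": {
  "ampelozizyphoid": [
   "Ampelozizyphus",
   "Bathiorhamnus"
  ],
  "rhamnoid": [
   "Berchemia",
   "Condalia",
   "Frangula",
   "Karwinskia",
   "Krugiodendron",
   "Reynosia",
   "Rhamnus",
   "Sageretia",
   "Scutia",
   "Ventilago"
  ],
  "Paliureae": [
   "Hovenia",
   "Paliurus",
   "Sarcomphalus",
   "Ziziphus"
  ],
  "Gouanieae": [
   "Gouania",
   "Helinus"
  ],
  "Colletieae": [
   "Colletia",
   "Discaria"
  ],
  "Phyliceae": [
   "Noltea",
   "Phylica"
  ],
  "Pomaderreae": [
   "Pomaderris"
  ],
  "ziziphoid": [
   "Ceanothus",
   "Colletia",
   "Discaria",
   "Gouania",
   "Helinus",
   "Hovenia",
   "Noltea",
   "Paliurus",
   "Phylica",
   "Pomaderris",
   "Sarcomphalus",
   "Ziziphus"
  ]
 }
}
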