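#NEXUS
[ SYNTHETIC stand-in for the MorphoBank P2506 matrix (24392): same
  shape (25 taxa x 30 characters, 25 floral + 5 foliar) but simulated
  Mk(3) characters, NOT the real observations.  Regenerate with
  scripts/build_fixtures.py ]

BEGIN DATA;
    DIMENSIONS NTAX=25 NCHAR=30;
    FORMAT DATATYPE=STANDARD SYMBOLS="012" MISSING=? GAP=-;
    MATRIX
    Ampelozizyphus  22?200210011002011?10201102120
    Bathiorhamnus   22011021001100200?220021121?00
    Berchemia       0002?012?201211210111101121112
    Ceanothus       ?201010?0202022202022011122000
    Colletia        12?200?02201000221212012022022
    Condalia        0?22122200021?1212022012201220
    Discaria        1?220202021120?201212002011202
    Frangula        00222001010201002022110200??22
    Gouania         2?02001222001121021011011?1112
    Helinus         210?0222220?212102120201020210
    Hovenia         1112002212?0121100112?21002200
    Karwinskia      12201100?022211012?20200201200
    Krugiodendron   112000210022111?121222222211?1
    Noltea          120102100?002222010100211001?1
    Notiantha       ?2??222{12}1??200?10?12{01}0010022??
    Paliurus        011202?20200122100222100?10201
    Phylica         ?1010220020022120211?101200012
    Pomaderris      120200110221012212?0011101200?
    Reynosia        ?2101120?021110012010020201221
    Rhamnus         ?0112?010102010020020101021102
    Sageretia       002?111101012111202?1110101122
    Sarcomphalus    011200220?01?20120222100220200
    Scutia          02222012202211011?00220?201200
    Ventilago       ?2010002020201212002120100?012
    Ziziphus        010?0222220012010212010012220?
    ;
END;

BEGIN SETS;
    CHARSET floral = 1-25;
    CHARSET foliar = 26-30;
END;
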