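#NEXUS

BEGIN DATA;
    DIMENSIONS NTAX=8 NCHAR=19;
    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
    CHARLABELS
        'fus_PAK1+PAK2' 'fus_PAK1+PAK4' 'fus_PAK3+PAK10' 'fus_PAK4+PAK10' 'fus_PAK6+PAK7' 'fus_PAK6+PAK7+PAK11' 'fus_PAK8+PAK9' fis_PAK1_x2 fis_PAK1_x3 fis_PAK1_x4 fis_PAK2_x2 fis_PAK2_x3 fis_PAK3_x2 fis_PAK6_x2 fis_PAK7_x2 fis_PAK10_x2 fis_PAK11_x2 'fus_PAK5+micro' 'fus_PAK10+micro'
    ;
    MATRIX
        AHY  0100101100000000010
        ACH  0100101100100001011
        PFR  0100100100000000000
        AMA  01001?1010000000?11
        MMO  1011111001011111100
        AAE  0000100100100000001
        GGA  0001000000000000000
        TRU  00000000000000000??
    ;
END;
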