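r,w,m,v
1,0.0058365755165777928,4.7664274674547533,4.3470506935020419
2,0.056663092733475799,2.9521202432711529,1.9403049866077224
3,0.18107401660142441,1.6872566086801561,0.95399064258460764
4,0.15016334727206601,1.1143500858820177,0.36344979383379783
5,0.11503724700501421,0.59531379720562561,0.20273158277370648
6,0.10592495684210489,0.23940662573233157,0.19653382194577732
7,0.10585749317571237,-0.057417986748514782,0.15005797899098081
8,0.10419235404016207,-0.30942821092174277,0.15836216306016854
9,0.10060865967157231,-0.64815836243656211,0.12263995404166435
10,0.074642257141890128,-1.085868303662852,0.14356091507545893
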