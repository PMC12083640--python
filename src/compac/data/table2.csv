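dx,bdr,ics,kw1,kw2,identified,covered,reviewed,confirmed
-,-,-,+,-,41759,105856,20,5
-,-,-,+,+,18761,51316,20,4
-,-,-,-,+,9548,61732,19,1
>=2,+,+,+,+,8555,8555,32,30
-,-,+,-,-,5502,28362,18,3
>=2,+,-,+,+,5084,13639,23,22
>=2,-,-,+,+,4727,21253,18,17
=1,-,-,+,-,4690,13453,21,14
=1,-,-,+,+,4417,7504,19,13
=1,-,-,-,-,4393,18855,19,10
-,-,+,+,-,3180,21698,21,9
>=2,-,+,+,+,2887,11442,20,20
-,-,+,+,+,2502,16473,20,14
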