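>MyoD myogenic E-box CAGCTG (synthetic consensus-derived matrix)
A  [  1 97  1  1  1  1 ]
C  [ 97  1  1 97  1  1 ]
G  [  1  1 97  1  1 97 ]
T  [  1  1  1  1 97  1 ]
>MyoG myogenin E-box AACAGCTG (synthetic consensus-derived matrix)
A  [ 97 97  1 97  1  1  1  1 ]
C  [  1  1 97  1  1 97  1  1 ]
G  [  1  1  1  1 97  1  1 97 ]
T  [  1  1  1  1  1  1 97  1 ]
>CTCF core CCGCGAGGTGGC (synthetic consensus-derived matrix)
A  [  1  1  1  1  1 97  1  1  1  1  1  1 ]
C  [ 97 97  1 97  1  1  1  1  1  1  1 97 ]
G  [  1  1 97  1 97  1 97 97  1 97 97  1 ]
T  [  1  1  1  1  1  1  1  1 97  1  1  1 ]
>Runx TGTGGTT (synthetic consensus-derived matrix)
A  [  1  1  1  1  1  1  1 ]
C  [  1  1  1  1  1  1  1 ]
G  [  1 97  1 97 97  1  1 ]
T  [ 97  1 97  1  1 97 97 ]
>AP-1 TPA-response element TGACTCA (synthetic consensus-derived matrix)
A  [  1  1 97  1  1  1 97 ]
C  [  1  1  1 97  1 97  1 ]
G  [  1 97  1  1  1  1  1 ]
T  [ 97  1  1  1 97  1  1 ]
>ATF3 CRE element TGACGTCA (synthetic consensus-derived matrix)
A  [  1  1 97  1  1  1  1 97 ]
C  [  1  1  1 97  1  1 97  1 ]
G  [  1 97  1  1 97  1  1  1 ]
T  [ 97  1  1  1  1 97  1  1 ]
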