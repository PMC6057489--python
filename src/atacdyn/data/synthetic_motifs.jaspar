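>MA9001.1 GATA3_SYN
A [  91   3  91   3  91  91   3  91 ]
C [   3   3   3   3   3   3   3   3 ]
G [   3  91   3   3   3   3  91   3 ]
T [   3   3   3  91   3   3   3   3 ]
>MA9002.1 RARG_SYN
A [  91   3   3   3   3  91  91   3   3   3   3  91 ]
C [   3   3   3   3  91   3   3   3   3   3  91   3 ]
G [   3  91  91   3   3   3   3  91  91   3   3   3 ]
T [   3   3   3  91   3   3   3   3   3  91   3   3 ]
>MA9003.1 REST_SYN
A [   3  91   3   3  91   3   3  91   3   3   3  91   3  91   3 ]
C [  91   3   3  91   3  91  91   3  91   3   3   3  91   3   3 ]
G [   3   3  91   3   3   3   3   3   3  91  91   3   3   3  91 ]
T [   3   3   3   3   3   3   3   3   3   3   3   3   3   3   3 ]
>MA9004.1 CTCF_SYN
A [   3   3   3   3   3  91   3   3   3   3   3   3  91   3 ]
C [  91  91   3  91   3   3   3   3   3   3   3  91   3   3 ]
G [   3   3  91   3  91   3  91  91   3  91  91   3   3  91 ]
T [   3   3   3   3   3   3   3   3  91   3   3   3   3   3 ]
>MA9005.1 SOX2_SYN
A [   3   3  91   3   3   3   3   3   3 ]
C [  91  91   3   3   3   3   3   3  91 ]
G [   3   3   3   3   3  91   3   3   3 ]
T [   3   3   3  91  91   3  91  91   3 ]
>MA9006.1 POU5F1_SYN
A [  91   3   3   3  91  91  91   3 ]
C [   3   3   3  91   3   3   3   3 ]
G [   3   3  91   3   3   3   3   3 ]
T [   3  91   3   3   3   3   3  91 ]
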