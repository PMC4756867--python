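MEROPS ID	UniProt	Cleavage position
A01.004	P05067	671
A01.009	P05067	705
A01.009	P05067	713
A01.009	P05067	714
A01.009	P05067	719
A01.009	P05067	720
A01.041	P05067	690
A01.041	P05067	691
A22.001	P05067	711
A22.001	P05067	713
A22.001	P05067	714
C01.060	P05067	704
C01.060	P05067	708
C01.060	P05067	711
C01.084	P05067	685
C01.084	P05067	685
C01.084	P05067	685
C01.084	P05067	689
C01.084	P05067	690
C01.084	P05067	690
C14.003	P05067	739
C14.005	P05067	672
C14.005	P05067	739
M02.001	P05067	711
M10.003	P05067	687
M10.003	P05067	705
M10.003	P05067	706
M10.004	P05067	687
M10.004	P05067	691
M10.004	P05067	694
M10.004	P05067	701
M10.004	P05067	704
M10.004	P05067	705
M10.014	P05067	579
M10.014	P05067	687
M10.016	P05067	463
M10.016	P05067	579
M10.016	P05067	622
M10.016	P05067	685
M10.017	P05067	685
M10.017	P05067	687
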