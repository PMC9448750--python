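Type	SBS1_like	SBS5_like	SBS18_like	SBS30_like	SBS40_like
A[C>A]A	0.00152174	0.01266993	0.04427902	0.0008984	0.01522681
A[C>A]C	0.00152174	0.0085016	0.02777679	0.0008984	0.01112006
A[C>A]G	0.00152174	0.00579546	0.04545279	0.0008984	0.01472746
A[C>A]T	0.00152174	0.00867325	0.04883956	0.0008984	0.01337599
C[C>A]A	0.00152174	0.01126162	0.046879	0.0008984	0.01498594
C[C>A]C	0.00152174	0.01111447	0.03214601	0.0008984	0.01294702
C[C>A]G	0.00152174	0.00990162	0.02992457	0.0008984	0.0165994
C[C>A]T	0.00152174	0.00560028	0.04825093	0.0008984	0.00787008
G[C>A]A	0.00152174	0.01016793	0.06786917	0.0008984	0.0084355
G[C>A]C	0.00152174	0.01034075	0.05471117	0.0008984	0.01138319
G[C>A]G	0.00152174	0.00647767	0.0444426	0.0008984	0.01455241
G[C>A]T	0.00152174	0.01126379	0.06391619	0.0008984	0.01321068
T[C>A]A	0.00152174	0.01216978	0.05925035	0.0008984	0.01007546
T[C>A]C	0.00152174	0.00799384	0.06027711	0.0008984	0.0081172
T[C>A]G	0.00152174	0.00705369	0.07402476	0.0008984	0.00949192
T[C>A]T	0.00152174	0.01054841	0.04545598	0.0008984	0.01576405
A[C>G]A	0.00152174	0.01256567	0.0025813	0.0008984	0.01362679
A[C>G]C	0.00152174	0.00710864	0.0025813	0.0008984	0.01281141
A[C>G]G	0.00152174	0.00620894	0.0025813	0.0008984	0.00806302
A[C>G]T	0.00152174	0.01219225	0.0025813	0.0008984	0.00745155
C[C>G]A	0.00152174	0.00761404	0.0025813	0.0008984	0.01350636
C[C>G]C	0.00152174	0.00833203	0.0025813	0.0008984	0.01327075
C[C>G]G	0.00152174	0.00640249	0.0025813	0.0008984	0.00997371
C[C>G]T	0.00152174	0.00847886	0.0025813	0.0008984	0.01315353
G[C>G]A	0.00152174	0.01240229	0.0025813	0.0008984	0.01139
G[C>G]C	0.00152174	0.01242018	0.0025813	0.0008984	0.01172326
G[C>G]G	0.00152174	0.01154853	0.0025813	0.0008984	0.00724384
G[C>G]T	0.00152174	0.0125428	0.0025813	0.0008984	0.01254436
T[C>G]A	0.00152174	0.00601954	0.0025813	0.0008984	0.00885477
T[C>G]C	0.00152174	0.00646536	0.0025813	0.0008984	0.00664487
T[C>G]G	0.00152174	0.00839081	0.0025813	0.0008984	0.01040145
T[C>G]T	0.00152174	0.00661758	0.0025813	0.0008984	0.01295824
A[C>T]A	0.00152174	0.01367847	0.0025813	0.04607174	0.0064642
A[C>T]C	0.00152174	0.00710575	0.0025813	0.04690941	0.01083158
A[C>T]G	0.14	0.00733877	0.0025813	0.0712061	0.01360773
A[C>T]T	0.00152174	0.01169071	0.0025813	0.0717804	0.00962821
C[C>T]A	0.00152174	0.01102109	0.0025813	0.04350036	0.0061775
C[C>T]C	0.00152174	0.0143048	0.0025813	0.04146457	0.00783356
C[C>T]G	0.11	0.01320306	0.0025813	0.06614354	0.00751777
C[C>T]T	0.00152174	0.01337484	0.0025813	0.07215106	0.01035101
G[C>T]A	0.00152174	0.00750216	0.0025813	0.03998723	0.00700789
G[C>T]C	0.00152174	0.01536732	0.0025813	0.04326368	0.01293796
G[C>T]G	0.09	0.00885377	0.0025813	0.06168691	0.00755452
G[C>T]T	0.00152174	0.01297476	0.0025813	0.08525548	0.00886853
T[C>T]A	0.00152174	0.01532114	0.0025813	0.04037422	0.01312299
T[C>T]C	0.00152174	0.01510312	0.0025813	0.0461339	0.01243767
T[C>T]G	0.51999992	0.00846873	0.0025813	0.0680075	0.00895764
T[C>T]T	0.00152174	0.00769737	0.0025813	0.0841919	0.00782807
A[T>A]A	0.00152174	0.00555233	0.0025813	0.0008984	0.00970897
A[T>A]C	0.00152174	0.01165043	0.0025813	0.0008984	0.01189364
A[T>A]G	0.00152174	0.00972411	0.0025813	0.0008984	0.00763256
A[T>A]T	0.00152174	0.00559949	0.0025813	0.0008984	0.00592694
C[T>A]A	0.00152174	0.01218488	0.0025813	0.0008984	0.00840476
C[T>A]C	0.00152174	0.00871417	0.0025813	0.0008984	0.01093655
C[T>A]G	0.00152174	0.00969069	0.0025813	0.0008984	0.01294219
C[T>A]T	0.00152174	0.01227268	0.0025813	0.0008984	0.00666148
G[T>A]A	0.00152174	0.00702977	0.0025813	0.0008984	0.00935036
G[T>A]C	0.00152174	0.00999383	0.0025813	0.0008984	0.01080699
G[T>A]G	0.00152174	0.01055685	0.0025813	0.0008984	0.00594749
G[T>A]T	0.00152174	0.01148705	0.0025813	0.0008984	0.00636203
T[T>A]A	0.00152174	0.00825398	0.0025813	0.0008984	0.00745062
T[T>A]C	0.00152174	0.00578175	0.0025813	0.0008984	0.01014235
T[T>A]G	0.00152174	0.01178531	0.0025813	0.0008984	0.00716898
T[T>A]T	0.00152174	0.01178132	0.0025813	0.0008984	0.00679744
A[T>C]A	0.00152174	0.01644839	0.0025813	0.0008984	0.0149374
A[T>C]C	0.00152174	0.01266063	0.0025813	0.0008984	0.01446518
A[T>C]G	0.00152174	0.01772351	0.0025813	0.0008984	0.00905982
A[T>C]T	0.00152174	0.01290567	0.0025813	0.0008984	0.01109138
C[T>C]A	0.00152174	0.01661425	0.0025813	0.0008984	0.01520712
C[T>C]C	0.00152174	0.01330525	0.0025813	0.0008984	0.01425488
C[T>C]G	0.00152174	0.01725398	0.0025813	0.0008984	0.01224963
C[T>C]T	0.00152174	0.00996862	0.0025813	0.0008984	0.01236538
G[T>C]A	0.00152174	0.01586294	0.0025813	0.0008984	0.01008731
G[T>C]C	0.00152174	0.0138646	0.0025813	0.0008984	0.00863699
G[T>C]G	0.00152174	0.01281561	0.0025813	0.0008984	0.01124676
G[T>C]T	0.00152174	0.01096156	0.0025813	0.0008984	0.00921532
T[T>C]A	0.00152174	0.01664213	0.0025813	0.0008984	0.01288889
T[T>C]C	0.00152174	0.01630813	0.0025813	0.0008984	0.01076585
T[T>C]G	0.00152174	0.01508326	0.0025813	0.0008984	0.01507713
T[T>C]T	0.00152174	0.015253	0.0025813	0.0008984	0.00889808
A[T>G]A	0.00152174	0.00731439	0.0025813	0.0008984	0.00731437
A[T>G]C	0.00152174	0.01227502	0.0025813	0.0008984	0.00753425
A[T>G]G	0.00152174	0.00682562	0.0025813	0.0008984	0.01222689
A[T>G]T	0.00152174	0.0088182	0.0025813	0.0008984	0.01195155
C[T>G]A	0.00152174	0.00697574	0.0025813	0.0008984	0.00939157
C[T>G]C	0.00152174	0.00568653	0.0025813	0.0008984	0.01095828
C[T>G]G	0.00152174	0.01095118	0.0025813	0.0008984	0.00889784
C[T>G]T	0.00152174	0.01090029	0.0025813	0.0008984	0.00704778
G[T>G]A	0.00152174	0.0064962	0.0025813	0.0008984	0.01352324
G[T>G]C	0.00152174	0.00913567	0.0025813	0.0008984	0.00876307
G[T>G]G	0.00152174	0.00872068	0.0025813	0.0008984	0.00788578
G[T>G]T	0.00152174	0.01024456	0.0025813	0.0008984	0.00603929
T[T>G]A	0.00152174	0.01029407	0.0025813	0.0008984	0.00730197
T[T>G]C	0.00152174	0.00864976	0.0025813	0.0008984	0.01173101
T[T>G]G	0.00152174	0.00701099	0.0025813	0.0008984	0.00689829
T[T>G]T	0.00152174	0.00612097	0.0025813	0.0008984	0.01132644
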