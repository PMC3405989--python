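gene,wt_q,wt_p,wt_period,wt_phase,wt_amplitude,rescue_q,rescue_p,rescue_period,rescue_phase,rescue_amplitude,hughes2009_rhythmic,kornmann_system_driven,kornmann_reanalysis_system_driven,lemartelot_reverba_target,rey_bmal_target
0610010D20Rik,0.043499,0.001074,26,9,1.3,0.019096,3.60E-05,26,7,1.7,YES,,,,
1110067D22Rik,0.000239,7.88E-07,24,22,4.1,0.005596,4.80E-06,24,21,1.5,YES,,,,
5630401D24Rik,0.035929,0.00079,26,10,1.3,0.08455,0.00079,26,11,1.4,,,,,
A630005I04Rik,0.000239,7.88E-07,24,22,10.6,0.04346,0.000216,22,21,1.8,YES,,,,
Abcb11,0.017929,0.000302,24,2,1.8,0.051058,0.000302,21,4.5,1.2,YES,,,,
Abcg5,0.000334,1.26E-06,22,11,2.8,0.063073,0.000419,26,6,1.5,YES,,,,
Abcg8,0.006556,7.56E-05,24,9,4.5,0.022227,5.24E-05,26,6,1.9,YES,,,,
Adarb1,0.003737,3.03E-05,24,12.5,2.0,0.08455,0.00079,24,12,1.3,,,,,YES
Adora1,7.02E-05,1.05E-07,26,9,1.8,0.08455,0.00079,26,9,1.4,YES,,,,
Agpat1,0.035929,0.00079,22,15,1.5,0.019096,3.60E-05,26,12,1.5,,,,,
Agtr1a,0.017929,0.000302,22,6,1.9,0.037685,0.000153,24,4,1.3,YES,,,,
AI842396,0.006556,7.56E-05,23,6.5,1.7,0.073204,0.000577,24,6,1.5,YES,,,,
Alas1,0.002233,1.66E-05,24,14,3.2,0.035038,0.000108,24,12,5.6,YES,,YES,,
Alpl,4.93E-05,6.13E-08,22,17,1.9,0.08455,0.00079,24,15,1.5,,,,,
Ankhd1,0.000175,4.87E-07,26,15,3.2,0.08455,0.00079,24,13.5,1.7,YES,,,,
Arl4a,0.010948,0.000153,24,22,2.1,0.019096,3.60E-05,22,2,1.3,YES,,,,
Arntl,4.93E-05,6.13E-08,24,23,34.5,0.019096,3.60E-05,24,21,2.2,YES,,,YES,YES
Atg2a,0.043499,0.001074,22,9,1.6,0.011737,1.11E-05,26,5,1.4,,,,,
Atp1a1,0.000903,4.80E-06,24,14.5,1.5,0.019096,3.60E-05,24,13,1.3,YES,,,,
BC016495,0.000133,2.96E-07,26,14,3.3,0.004223,1.99E-06,28,14,2.0,YES,,,,YES
Cabc1,0.000334,1.26E-06,24,1,4.0,0.011737,1.11E-05,22,4,1.8,YES,,YES,YES,YES
Camk1d,0.00861,0.000108,24,0,2.4,0.04346,0.000216,22,2,2.3,YES,,,,
Ccng2,0.010948,0.000153,24,22,2.3,0.04346,0.000216,24,0,1.7,YES,,,,
Ccrn4l,0.00046,1.99E-06,24,14,4.1,0.08455,0.00079,22,13,7.4,YES,YES,,,YES
Celsr1,0.00046,1.99E-06,24,21,2.3,0.04346,0.000216,24,18,1.9,YES,,,,
Chkb,0.005073,5.24E-05,22,4,1.6,0.037685,0.000153,22,3,1.4,YES,,,,
Clpx,1.38E-05,5.92E-09,24,23,7.4,0.001228,6.13E-08,24,23,2.0,YES,,,YES,
Coq10b,0.000334,1.26E-06,24,13,3.9,0.04346,0.000216,24,13,2.7,,,,,YES
Crot,0.000175,4.87E-07,22,5,2.7,0.022227,5.24E-05,22,5,1.6,YES,,,,
Dapk1,0.003837,3.60E-05,24,23,2.6,0.08455,0.00079,22,21,1.5,YES,,,,YES
Dbp,7.02E-05,1.05E-07,24,11,10.7,0.04346,0.000216,24,9,1.6,YES,,YES,,YES
Enpp2,0.003061,2.45E-05,24,13,1.8,0.08455,0.00079,22,11,1.4,YES,,,,
Etnk2,0.000334,1.26E-06,24,12,1.5,0.099034,0.001074,24,11,1.9,YES,,,,YES
Fbxo21,0.003837,3.60E-05,22,8,2.9,0.037685,0.000153,24,5,1.8,YES,YES,,,YES
Fkbp4,0.017929,0.000302,24,19,1.7,0.012876,1.66E-05,24,16,1.7,YES,,,,
Fmo5,0.000239,7.88E-07,22,17,2.1,0.04346,0.000216,24,15,1.5,YES,,,YES,YES
Gabarapl1,0.017929,0.000302,22,7,2.0,0.037685,0.000153,24,4,1.8,YES,,,,
Gpt2,0.000175,4.87E-07,24,14,1.9,0.022227,5.24E-05,22,13,1.6,YES,,,,YES
Hlf,0.000239,7.88E-07,24,14,2.3,0.004223,1.99E-06,24,13,1.6,YES,,,,YES
Ivns1abp,0.028179,0.000577,24,14.5,1.6,0.063073,0.000419,24,13,1.4,YES,,,,YES
Kcnk5,0.002233,1.66E-05,24,13,3.1,0.063073,0.000419,22,11,3.2,YES,,,,
Klf15,0.006556,7.56E-05,24,12,1.5,0.051058,0.000302,24,12,1.6,YES,,,,YES
Mad2l2,0.000175,4.87E-07,24,2,3.0,0.035038,0.000108,22,3,1.4,YES,,,,
Man2a1,0.010948,0.000153,24,14,1.6,0.012876,1.66E-05,24,14,1.4,,,,,YES
Mapk14,0.001229,7.32E-06,24,16,1.6,0.08455,0.00079,24,14.5,1.3,YES,,,,
Marveld1,1.96E-05,1.09E-08,24,15,2.1,0.016353,2.45E-05,24,13,1.7,YES,,,,YES
Mfsd2,0.000903,4.80E-06,24,14,7.3,0.099034,0.001074,24,12.5,6.2,YES,,,,
Mgrn1,0.001229,7.32E-06,24,10,1.5,0.073204,0.000577,28,5,1.3,YES,,,,YES
Mov10,0.013737,0.000216,22,8,1.9,0.005596,4.80E-06,26,4,1.9,,,,,
Mpzl1,0.001624,1.11E-05,24,0,2.6,0.073204,0.000577,22,2,1.4,YES,,,,
Mreg,0.000133,2.96E-07,22,2,2.3,0.08455,0.00079,22,2,1.4,,,,,
Mthfr,1.38E-05,5.92E-09,24,23,3.3,0.099034,0.001074,24,20,1.2,YES,,,,
Mtss1,0.00861,0.000108,24,12,2.1,0.001384,1.78E-07,24,13,2.6,YES,,,,YES
Ndrg1,0.000133,2.96E-07,24,2.5,2.4,0.063073,0.000419,20,5,2.3,YES,,,YES,
Npas2,3.72E-05,3.51E-08,24,1,2.7,0.037685,0.000153,24,22,3.3,YES,,,,
Nr1d1,4.93E-05,6.13E-08,26,7,12.3,0.037685,0.000153,24,6,1.7,YES,,,YES,YES
Nr1d2,1.96E-05,1.09E-08,24,10.5,11.3,0.037685,0.000153,24,8,2.7,YES,,YES,,YES
P2rx4,0.013737,0.000216,23,10.5,1.7,0.063073,0.000419,28,4,1.6,YES,,,,
Park2,0.000631,3.11E-06,26,8,1.5,0.003676,1.26E-06,26,7,1.7,,,,,
Per1,0.000133,2.96E-07,24,13,4.3,0.022227,5.24E-05,22,12,3.7,YES,,,,YES
Per2,4.78E-06,4.10E-10,24,15,5.9,0.005596,4.80E-06,24,13,5.0,YES,YES,,,YES
Per3,0.000175,4.87E-07,24,13,11.2,0.003676,7.88E-07,24,12.5,2.5,YES,,,,YES
Pex26,0.003061,2.45E-05,26,12,1.6,0.037685,0.000153,24,12.5,1.3,YES,,,,YES
Pik3ap1,0.010948,0.000153,24,8,2.1,0.022227,5.24E-05,24,9,1.5,YES,,,,YES
Pla2g12a,0.006556,7.56E-05,22,11,2.3,0.073204,0.000577,24,8,1.6,YES,,,,YES
Por,6.35E-06,1.63E-09,24,14,3.5,0.04346,0.000216,24,13,1.6,YES,,,YES,
Ppp1r3b,0.013737,0.000216,24,18.5,3.8,0.051058,0.000302,24,14,1.9,YES,,,,YES
Rhbdd2,0.000334,1.26E-06,24,14,2.3,0.016353,2.45E-05,26,11,1.4,YES,,,,
Rnf125,0.010948,0.000153,22,2,4.9,0.003676,1.26E-06,22,2,4.4,YES,,,,YES
Scap,0.00046,1.99E-06,22,8,1.6,0.08455,0.00079,26,3,1.5,YES,,,,YES
Serpinf2,0.013737,0.000216,22,7,1.4,0.063073,0.000419,24,5,1.4,YES,,,,
Sh3bp2,0.043499,0.001074,26,8,1.2,0.099034,0.001074,28,6,1.3,YES,,,,
Slc17a3,0.017929,0.000302,24,21,2.1,0.037685,0.000153,26,16,1.7,YES,,,,YES
Slc37a4,0.000175,4.87E-07,24,14,1.7,0.037685,0.000153,22,13,2.5,YES,,,,
Slc5a6,0.00861,0.000108,24,11,2.1,0.051058,0.000302,24,11,1.5,YES,,,,YES
Spon2,6.48E-05,8.33E-08,22,3,2.9,0.005578,3.11E-06,24,1,2.0,YES,,,,
Srm,0.005073,5.24E-05,22,16,1.8,0.035038,0.000108,24,13.5,2.2,YES,,,,YES
St3gal5,0.000631,3.11E-06,24,14.5,3.2,0.028443,7.56E-05,24,11,2.4,YES,,,,YES
St5,0.001624,1.11E-05,24,23,5.6,0.022227,5.24E-05,22,0,1.7,,,,,
Syt1,0.013737,0.000216,24,9,3.4,0.001728,2.96E-07,24,6,1.9,YES,,,,
Tef,3.72E-05,3.51E-08,24,12,7.0,0.005578,3.11E-06,24,13,2.0,YES,,,,YES
Tmem218,0.001624,1.11E-05,26,1,3.1,0.001228,1.05E-07,22,2,1.8,,,,YES,
Tns1,0.02232,0.000419,22,15,1.8,0.012876,1.66E-05,24,12,1.5,,,,,YES
Tsc22d3,0.002233,1.66E-05,24,17,2.6,0.063073,0.000419,22,13,3.1,YES,,,YES,YES
Ubxn1,0.000175,4.87E-07,22,5,2.0,0.012876,1.66E-05,22,5,1.6,,,,YES,
Ulk1,0.010948,0.000153,22,9,1.9,0.08455,0.00079,24,4,1.2,YES,,,,
Usp2,0.000631,3.11E-06,24,13,15.9,0.019096,3.60E-05,24,13,4.5,YES,,,,YES
Wbscr27,0.00861,0.000108,24,5,1.8,0.037685,0.000153,24,4,1.5,YES,,,,
Wdr45,0.010948,0.000153,22,9,1.5,0.051058,0.000302,24,6,1.7,YES,,,,
Wrnip1,0.006556,7.56E-05,24,0,1.8,0.005596,4.80E-06,22,3,1.6,YES,,,,YES
Ypel2,0.017929,0.000302,24,22.5,3.6,0.022227,5.24E-05,22,2,2.8,,,,,
Zfp295,9.88E-05,1.78E-07,24,21,1.7,0.028443,7.56E-05,24,17,1.4,YES,,,,
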