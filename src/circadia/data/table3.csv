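probe_set_id,gene,wt_p,wt_fdr,wt_period,wt_phase,rescue_p,rescue_fdr,rescue_period,rescue_phase,mutant_p,mutant_fdr,mutant_period,mutant_phase
6837437,Arfgap3,0.027,0.45,12,2.0,0.034,0.61,22,11.0,1.00,1.0,28.4,16.9
6800427,Dnajb9,0.003,0.08,12,2.0,0.286,1.0,20,12.0,1.00,1.0,28.4,17.5
6992306,Gmppb,3.02E-04,0.02,12,2.0,7.56E-05,0.03,24,13.0,1.00,1.0,28.4,15.1
6997671,Tmed3,0.043,0.61,12,3.0,0.003,0.18,24,12.0,0.193,1.0,12,1.0
6992409,Nme6,0.054,0.71,12,3.0,0.001,0.10,24,12.0,1.00,1.0,28.4,15.5
6998396,Srprb,0.003,0.10,12,3.0,2.16E-04,0.04,24,12.5,1.00,1.0,28.4,16.4
6832530,Creld2,0.010,0.22,12,3.0,1.26E-06,0.004,24,13.0,1.00,1.0,28.4,16.1
6876342,Hspa5,0.001,0.04,12,3.0,1.53E-04,0.38,24,13.0,0.235,1.0,30,27.0
6807251,Tmed9,0.068,0.82,12,3.0,0.006,0.24,24,13.0,1.00,1.0,28.4,15.1
6881837,Sec23b,2.45E-05,0.003,12,3.0,0.001,0.10,24,13.0,0.416,1.0,12,0.0
6817412,Samd8,0.005,0.12,12,7.0,0.104,1.0,20,5.0,1.00,1.0,28.4,9.4
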