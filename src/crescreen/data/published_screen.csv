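receptor,group,notes
GPR15,A,
GPR17 variant 3,A,
GPR18,A,
GPR20,A,
GPR25,A,
GPR27,A,
GPR31,A,
GPR32,A,
GPR45,A,
GPR55,A,listed in group A in the detailed results; absent from the abstract's roster
GPR57 variant 1,A,
GPR68,A,
GPR83,A,
GPR84,A,
GPR132,A,
GPR150,A,
GPR176,A,
GPR6,B,
GPR12,B,
GPR4,C,
GPR26,C,
GPR61,C,
GPR62,C,
GPR78,C,
GPR101,C,
GPR119,C,
GPR3,D,forskolin-response inhibition large but not significant (p = 0.072); criterion 3 not counted
GPR21,D,
GPR52,D,
GPR65,D,
GPR1,E,
GPR19,E,
GPR22,E,
GPR34,E,
GPR35,E,
GPR39,E,
GPR63 variant 2,E,
GPR82,E,
GPR85,E,
GPR87,E,
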