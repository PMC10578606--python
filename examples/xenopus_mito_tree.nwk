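(X_tropicalis,(X_muelleri,(X_clivii,((X_pygmaeus,(X_itombwensis,(X_kobeli,X_andrei))),(X_vestitus,(X_largeni,((X_gilli,X_laevis),(X_petersii,(X_poweri,X_victorianus)))))))));
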