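class,icd10_prefix
statins,I20.0
statins,I21
statins,I22
statins,I60
statins,I61
statins,I62
statins,I63
statins,I64
statins,I65
statins,I66
statins,I67
statins,I68
statins,I69
statins,I70
antiplatelets,I60
antiplatelets,I61
antiplatelets,I62
antiplatelets,I63
antiplatelets,I64
antiplatelets,G45
antiplatelets,I21
antiplatelets,I22
breast_cancer,C50
doac,I48
doac,I26
doac,I80
doac,I87.1
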