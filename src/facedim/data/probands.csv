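group,sex,n,mean,sd,variable
proband,male,54,14.5,2.69,masculinity_score
proband,female,20,6.81,2.56,masculinity_score
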