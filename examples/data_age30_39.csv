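n,mean,sd
85,160.27,28.37
80,177.08,23.22
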