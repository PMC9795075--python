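n_classes,loglik,n_parameters,n,aic,bic,entropy
2,-2388,155,108,5087,5502,4.68
3,-2312,233,108,5089,5715,4.68
4,-2299,311,108,5220,6054,4.68
5,-2245,389,108,5267,6310,4.68
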