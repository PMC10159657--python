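# SYNTHETIC class-I pseudo-sequence panel (generated stand-ins, not
# IMGT/HLA-derived); allele<TAB>34-aa pseudo-sequence.
HLA-A*01:01	MKEHVPHTNFPQHLMHCNHAIWYIDLTVMYAYDI
HLA-B*01:01	SQHRCPWSKWGTWEDAGHFALQGMEQIKYRVFEE
HLA-C*01:01	VWYDDFHVEWRYNIRFTLWICHVLLTAIVLDDVW
HLA-A*02:01	NDWLVYQIWNLQVCFCNCTTNLTGNLCAIMTEHK
HLA-B*02:01	SKNSRLFSNKFIDYIMQVPNTCEVYWYVCIFGTH
HLA-C*02:01	YEVVIYRTRSLKDRQFFTPNDNKANRCSQQGWVI
HLA-A*03:01	QTKAHLERGDWSQGCFYQMRKWYFQTTEQNQCSI
HLA-B*03:01	LYPFKFIMEHPMDWPMILMDKKVKEVVKPWSHWC
HLA-C*03:01	SHFDIFDEWMIFTAKYPDAGKRWEQLIRECNPVS
HLA-A*04:01	TPADLRLNMRGWICSLIADWRNASICNDEWCITS
HLA-B*04:01	CVPQNIVISARACKEVAKPADFVFYCEGKPYVNA
HLA-C*04:01	YAYMKNNWMWFRTKPVMGAHKTYHINTRSDVTCA
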