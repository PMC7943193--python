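substitution	label	source
H6R	dominant_fAD	alzforum APP mutation table (English)
D7N	dominant_fAD	alzforum APP mutation table (Tottori)
D7H	dominant_fAD	alzforum APP mutation table (Taiwanese)
E11K	dominant_fAD	alzforum APP mutation table (Leuven)
K16N	dominant_fAD	alzforum APP mutation table
A21G	dominant_fAD	alzforum APP mutation table (Flemish)
E22G	dominant_fAD	alzforum APP mutation table (Arctic)
E22K	dominant_fAD	alzforum APP mutation table (Italian)
E22Q	dominant_fAD	alzforum APP mutation table (Dutch)
D23N	dominant_fAD	alzforum APP mutation table (Iowa)
L34V	dominant_fAD	alzforum APP mutation table (Piedmont)
A42T	dominant_fAD	alzforum APP mutation table
A2V	recessive_fAD	alzforum APP mutation table
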