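# Default rule lexicon for pneumothorax report labeling.
# One rule per line: term <TAB> category. Multi-word terms allowed.
# Categories: mention, negation, size_large, size_small.
pneumothorax	mention
pneumothoraces	mention
ptx	mention
hydropneumothorax	mention
no	negation
without	negation
negative for	negation
free of	negation
resolution of	negation
absence of	negation
large	size_large
moderate	size_large
sizable	size_large
extensive	size_large
small	size_small
tiny	size_small
trace	size_small
subtle	size_small
minimal	size_small
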