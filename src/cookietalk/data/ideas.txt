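children stealing cookies
woman doing dishes
girl reaching for a cookie
woman not noticing
boy on stool
sink overflowing
stool falling
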